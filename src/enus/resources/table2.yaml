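# Default hyperparameters for the eight benchmarked models.
# Keys are model ids; values override the built-in defaults (see
# enus.models.TABLE_DEFAULTS). An empty map keeps all defaults.
kNN:
  k: 20
DT:
  cp: 0.01
  tune_length: 10
RF:
  mtry: 3
  ntree: 500
NNet:
  init_rand_weight: 0.5
  decay: 0.0005
  max_iteration: 5000
  activation_func: ReLU
NNet-ML:
  hidden_layer_num: 8
  max_step: 100000
  learning_rate: 0.1
  threshold: 0.01
  activation_func: ReLU
SVM:
  method: svmRadial
  gamma: 0.1
  cost: 1.0
XGBTree:
  learning_rate: 0.01
  max_depth: 5
  gamma: 3
XGBTree-Grid:
  learning_rate: 0.1
  max_depth: 7
  gamma: 5
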