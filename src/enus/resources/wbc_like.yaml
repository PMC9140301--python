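# Default recipe for Wisconsin-like synthetic data: nine 1-10 ordinal
# features, ~65:35 class imbalance, separated class-conditional means,
# one strongly rank-correlated pair and two weak features.
n_total: 700
imbalance_ratio: 0.54
negative_class: B
positive_class: M
round_to_ordinal: true
value_range: [1, 10]
class_scales:
  B: 1.1
  M: 2.4
weak_location: 3.0
weak_scale: 2.0
correlated_pair: [Cell_Shape, Cell_Size, 0.91]
feature_names:
  - Clump_Thickness
  - Cell_Size
  - Cell_Shape
  - Adhesion
  - Epi_Cell_Size
  - Nuclei
  - Chromatin
  - Nucleoli
  - Mitoses
class_locations:
  B:
    Cell_Size: 1.9
    Cell_Shape: 1.9
    Adhesion: 1.9
    Epi_Cell_Size: 1.9
    Nuclei: 1.9
    Chromatin: 1.9
    Nucleoli: 1.9
  M:
    Cell_Size: 5.5
    Cell_Shape: 5.5
    Adhesion: 5.5
    Epi_Cell_Size: 5.5
    Nuclei: 5.5
    Chromatin: 5.5
    Nucleoli: 5.5
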