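# Default association scoring table: score in 0..4 from (number of studies,
# proportion of positive results).  Band edges are lower-inclusive.  The cell
# matrix must be monotone non-decreasing along both axes; it is validated at
# load.  Score 0 is forced whenever n_studies = 0.  Replace this file to use a
# different two-criteria cutoff table.
study_bands: [1, 3, 6, 11]        # band edges: [0], [1,2], [3,5], [6,10], [11,inf)
proportion_bands: [0.25, 0.5, 0.75]  # [0,.25), [.25,.5), [.5,.75), [.75,1]
scores:                           # rows = study bands, cols = proportion bands
  - [0, 0, 0, 0]
  - [1, 1, 1, 1]
  - [1, 2, 2, 2]
  - [1, 2, 3, 3]
  - [1, 2, 3, 4]
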