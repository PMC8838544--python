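# Default metric-to-score maps for the data-driven dQAS items.
#
# Each map is a list of [lower, upper, score] half-open intervals [lower,
# upper) partitioning the metric's range ("inf" = unbounded above). The DESR
# map is anchored so that the NAIIS throughput (13 personnel per 1000 records
# per day) scores 2 on the 0-3 scale; a higher DESR means better staffing and
# never a lower score. The VMR/OMR/duplicate maps are decreasing in the
# ratio: cleaner data never scores lower. Deployments may supply their own
# cut-points; these defaults are data, not code.
desr:
  direction: higher_is_better
  intervals:
    - [0, 5, 0]
    - [5, 10, 1]
    - [10, 20, 2]
    - [20, inf, 3]
vmr:
  direction: lower_is_better
  intervals:
    - [0.0, 0.01, 4]
    - [0.01, 0.05, 3]
    - [0.05, 0.10, 2]
    - [0.10, 0.20, 1]
    - [0.20, inf, 0]
omr:
  direction: lower_is_better
  intervals:
    - [0.0, 0.01, 4]
    - [0.01, 0.05, 3]
    - [0.05, 0.10, 2]
    - [0.10, 0.20, 1]
    - [0.20, inf, 0]
duplicate_ratio:
  direction: lower_is_better
  intervals:
    - [0.0, 0.01, 1]
    - [0.01, inf, 0]
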