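# Reference data

The original long-range feeder-training dataset (per-dance mean durations of
56 dances, one per bee, at nine feeder distances from 0.1 to 1.7 km) is
distributed as supplementary material of the study that established the
calibrations bundled in this package. It is **not redistributed here**.

To run the reference-data checks in `tests/test_acceptance.py`, download the
per-dance summary table from the study's data deposit and save it as

    data/study_dances.csv

in the summarized CSV layout the readers auto-detect:

| column        | meaning                             |
|---------------|-------------------------------------|
| `bee_id`      | unique label of the dancing bee     |
| `distance_km` | feeder distance from the hive (km)  |
| `waggle_s`    | mean waggle-phase duration (s)      |
| `return_s`    | mean return-phase duration (s)      |
| `circuit_s`   | mean circuit duration (s)           |

All other tests, and `scripts/acceptance.py`, use the package's own
synthetic-data generator and run without any download.
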