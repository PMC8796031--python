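"""Full pipeline: regularization sweep with resection-referenced scoring.

Runs simulate -> filter -> average -> localize for three methods, three
modalities and two head-model conductivity profiles over the diagonal
loading grid, then prints the best (argmin-distance) cell per combination.
"""

import warnings

from spikebeam import run_pipeline

warnings.filterwarnings("ignore")

bundle = run_pipeline({
    "seed": 1,
    "sensors": {"n_eeg": 60, "n_meg": 100},
    "grid": {"spacing_mm": 12.0},
    "source": {"n_trials": 54, "srate": 600.0},
    "sweep": {"alphas": [0.0, 0.01, 0.02, 0.05, 0.1, 0.2]},
})

print("argmin-distance summary (alpha minimizing the resection distance):")
print(bundle["summary"].to_string(index=False))
fr = bundle["records"]
n_err = fr["error"].notna().sum()
print(f"\n{len(fr)} sweep cells, {n_err} failed "
      "(failures, if any, are unregularized rank-deficient covariances)")
print("resection distance 0.0 means the map maximum fell inside the "
      "resection volume; relative power < 1 marks a confident inside "
      "localization")
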