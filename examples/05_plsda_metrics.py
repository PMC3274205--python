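"""PLS-DA: latent-variable selection and per-class merit figures.

Spectra are regressed on one-hot class indicators; the latent-variable
count is chosen by venetian-blind cross-validation with the one-standard-
error rule, and a spectrum is assigned to the class with the largest
predicted indicator.  Sensitivity = predicted-in-class / actually-in-class;
specificity = predicted-not-in-class / actually-not-in-class.
"""

from ramanforensiq import CvScheme, plsda_evaluate, plsda_train, simulate_dataset
from ramanforensiq.pipeline import ExperimentConfig, preprocess
from ramanforensiq.synthetic import SimulationConfig

cfg = ExperimentConfig(simulation=SimulationConfig(seed=42))
data = preprocess(simulate_dataset(cfg.simulation), cfg)

scheme = CvScheme("venetian_blind", n_splits=10)
model = plsda_train(data, scheme=scheme)
print(f"selected latent variables: {model.a}")

cal, cv = plsda_evaluate(model, data, scheme)
print(f"{'class':8s} {'sens(Cal)':>9s} {'spec(Cal)':>9s} "
      f"{'sens(CV)':>9s} {'spec(CV)':>9s} {'RMSEC':>7s} {'RMSECV':>7s}")
for c in cal.classes:
    print(f"{c:8s} {cal.sensitivity[c]:9.3f} {cal.specificity[c]:9.3f} "
          f"{cv.sensitivity[c]:9.3f} {cv.specificity[c]:9.3f} "
          f"{cal.rmse[c]:7.4f} {cv.rmse[c]:7.4f}")
print("-> Cal rows are self-prediction; CV rows refit the model inside each")
print("   fold, so they estimate performance on unseen spectra.")
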