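"""Compare the three gait-phase classifiers on one synthetic recording.

SVM (RBF kernel, one-vs-one), Fisher LDA (nearest projected centroid) and
an extreme learning machine are trained on the same 70/30 stratified
split; per-phase recognition rates and their unweighted mean are printed
for each.
"""

from emgait import (GaitCycleSpec, extract_features, generate_recording,
                    per_phase_rates, predict_elm, predict_lda, predict_svm,
                    sliding_windows, split, train_elm, train_lda, train_svm,
                    well_separated_profiles)

rec = generate_recording(well_separated_profiles(),
                         GaitCycleSpec(n_cycles=15), noise_sd=0.05, seed=3)
fm = extract_features(sliding_windows(rec, 128, 64), families=("T", "W"))
train, test = split(fm, train_fraction=0.7, seed=0)
x_tr, y_tr = train.to_numpy(), train.labels
x_te, y_te = test.to_numpy(), test.labels

models = {
    "SVM (C=10, g=10)": lambda: predict_svm(train_svm(x_tr, y_tr, 10, 10), x_te),
    "LDA": lambda: predict_lda(train_lda(x_tr, y_tr), x_te),
    "ELM (L=100)": lambda: predict_elm(train_elm(x_tr, y_tr, 100, seed=0), x_te),
}
print(f"{len(train)} training / {len(test)} test windows\n")
print(f"{'classifier':>18}  prestance midstance term.stance preswing  overall")
for name, fit_predict in models.items():
    rep = per_phase_rates(y_te, fit_predict())
    phases = "  ".join(f"{v:8.2f}" for v in rep.per_phase)
    print(f"{name:>18}  {phases}  {rep.overall:7.2f}")
print("\noverall is the unweighted mean of the four per-phase rates.")
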