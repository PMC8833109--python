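"""Train elastic-net ageing clocks on each assay, plus core and mega clocks.

Each clock regresses chronAge on one assay's standardised features
(alpha = 0.5 mixing, lambda at minimum tenfold-CV MSE, 75/25 split with
test individuals drawn from those complete on every assay). A "core"
clock refits on features selected in >95% of repeated re-splits; the
"mega" clock sees every feature of every assay at once.
"""

from omiclocks import (build_mega_matrix, default_config, qc_pipeline,
                       mega_selection_shares, simulate_cohort, split_cohort,
                       stability_select, train_clock)

cfg = default_config(seed=1, n_individuals=1000)
study = simulate_cohort(cfg)
chron_age = study.cohort["chron_age"]

corrected = [qc_pipeline(m)[0] for m in study.omics]
complete = set(study.cohort.index)
for m in corrected:
    complete &= set(m.complete_ids())
train_ids, test_ids = split_cohort(study.cohort.index,
                                   complete_ids=sorted(complete), seed=1)

print(f"{'clock':14s} {'n':>5s} {'p_avail':>8s} {'p_sel':>6s} "
      f"{'train_r':>8s} {'test_r':>7s}")
for m in corrected:
    model = train_clock(m, chron_age, train_ids, test_ids, n_lambdas=50,
                        seed=1)
    print(f"{m.assay_name:14s} {m.n_individuals:5d} {m.n_features:8d} "
          f"{model.n_selected:6d} {model.train_r:8.2f} {model.test_r:7.2f}")

mega = build_mega_matrix(corrected)
model = train_clock(mega, chron_age, train_ids, test_ids, n_lambdas=50,
                    seed=1)
print(f"{'mega':14s} {mega.n_individuals:5d} {mega.n_features:8d} "
      f"{model.n_selected:6d} {model.train_r:8.2f} {model.test_r:7.2f}")
shares = mega_selection_shares(model)
print("mega clock feature shares by assay:",
      {k: f"{v:.1%}" for k, v in sorted(shares.items())})

# Stability selection on the most informative assay: a substantially
# subset core panel should lose very little accuracy.
result, core = stability_select(corrected[0], chron_age, iterations=100,
                                n_lambdas=30, seed=1,
                                final_split=(train_ids, test_ids))
print(f"\ncore {corrected[0].assay_name}: {len(result.core_features)} stable "
      f"features (of {corrected[0].n_features}), test_r {core.test_r:.2f}")
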