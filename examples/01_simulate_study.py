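"""Build the five-model synthetic knockout islet study.

Three LKB1-null and two AMPK-null strains, each with 3 KO and 3 WT
replicate libraries; planted neuronal/hepatic up-regulation in the
LKB1-null models, disallowed-gene up-regulation in the AMPK-null models,
and a strongly induced core group shared by all five.
"""

import isletkit as ik

config = ik.default_config(seed=1)
study, truth = ik.simulate_counts(config)

print(f"{config.n_genes} genes, {len(config.models)} models, "
      f"~{config.library_size:,} reads per library\n")
for name, cm in study.models.items():
    n_absent = int(cm.absent.sum())
    print(f"{name:>18}: {cm.counts.shape[1]} samples, "
          f"{n_absent} genes absent from this model")

print("\nplanted groups (genes, fold, affected kinase groups):")
for grp in config.planted_groups:
    print(f"  {grp.name:>12}: {grp.n_genes:3d} genes x {grp.fold_effect}-fold in {grp.kinases}")

members = truth.group_members("neuronal")[:3]
print(f"\nexample truth rows for neuronal genes {members}:")
print(truth.fold_changes.loc[members].to_string())
# each row is that gene's true KO/WT fold change per model: 3.0 where the
# LKB1-null effect is planted, 1.0 in the AMPK-null models.
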