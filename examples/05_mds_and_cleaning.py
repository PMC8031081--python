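"""Diagnostics: classical MDS maps, outlier flagging, and subgroup splitting.

Classical (Torgerson) MDS of the descriptor vectors shows how ligand groups
occupy descriptor space.  The cleaning tools replace by-eye outlier removal
with a reproducible chi-square tail rule, and heterogeneous groups can be
split into subgroups by k-means for model building (evaluation merges the
sublabels back).
"""

import warnings

import numpy as np

import cdpa

warnings.filterwarnings("ignore")

dataset = cdpa.make_preset_dataset("default", seed=1)
vectors = cdpa.encode_sites(dataset.sites)

# --- MDS map ---------------------------------------------------------------
embedding = cdpa.classical_mds(vectors, k=2)
top = embedding.eigenvalues[:4]
print("MDS eigenvalues (top 4):", np.round(top, 1))
print("variance captured by 2 axes:",
      f"{top[:2].sum() / embedding.eigenvalues[embedding.eigenvalues > 0].sum():.1%}")

from cdpa.plotting import plot_mds

plot_mds(embedding, labels=dataset.labels, path="mds_groups.png")
print("wrote mds_groups.png (sites colour-coded by ligand group)\n")

# --- outlier flagging -------------------------------------------------------
by_group = {}
for v, l in zip(vectors, dataset.labels):
    by_group.setdefault(l, []).append(v)
# plant one gross outlier in the PO4 group
bad = cdpa.CDPAVector(v=by_group["PO4"][0].v + 500.0, site_id="syn-PO4-bad")
by_group["PO4"] = by_group["PO4"] + [bad]
# with a sample covariance, a point's squared Mahalanobis distance cannot
# exceed ~(n-1)²/n, so in a 21-member group the 0.999 chi-square(6) quantile
# (22.5) is unreachable; a milder alpha is appropriate for small groups
report = cdpa.flag_outliers(by_group, alpha=0.01)
print("outlier flags (chi-square(6) tail, alpha=0.01, threshold "
      f"{report.threshold:.1f}):")
print({g: f for g, f in report.flagged.items() if f})

# --- subgroup splitting -----------------------------------------------------
hem = by_group["HEM"]
split = cdpa.split_subgroups(hem, "HEM", k=2, seed=0)
counts = {}
for sub in split.subgroups.values():
    counts[sub] = counts.get(sub, 0) + 1
print("\nHEM split for model building:", counts)
print("(evaluation always merges HEM-I/HEM-II back to HEM via a merge map)")
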