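"""2^3 full-factorial differential expression with effect-size gates.

Expression is profiled over a sex x genotype x organ design (two levels
each, uniform replication).  Per probe, the omnibus test is the F test of
the saturated fixed-effects factorial model — computed as the one-way ANOVA
across the 8 design cells, to which it is algebraically identical — followed
by Benjamini-Hochberg adjustment across probes.  Differential calls then
pass through explicit log2 fold-change gates:

* multivariate significant: FDR q below ``fdr_alpha`` and some group's
  |log2FC versus the grand mean| above ``snr_lfc`` (the signal-to-noise > 1
  threshold, 0.286 by default);
* pairwise differential: additionally a Welch post hoc p below
  ``posthoc_alpha`` and |pairwise log2FC| above the 5% practical-difference
  threshold ``practical_lfc`` (0.094);
* robust: pairwise differential with |pairwise log2FC| above ``snr_lfc``.

Downstream, significant probes feed a sample-space PCA and curated
differential probes feed correlation-distance average-linkage clustering
into expression patterns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from scipy import stats

FACTORS = ("sex", "genotype", "organ")
LEVELS = {"sex": ("M", "F"), "genotype": ("WT", "KO"), "organ": ("Cb", "Br")}


@dataclass
class DEConfig:
    fdr_alpha: float = 0.05
    snr_lfc: float = 0.286
    practical_lfc: float = 0.094
    posthoc_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.fdr_alpha < 1 and 0 < self.posthoc_alpha < 1):
            raise ValueError("alphas must lie in (0, 1)")
        if min(self.snr_lfc, self.practical_lfc) <= 0:
            raise ValueError("log2FC thresholds must be > 0")


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check the design is full factorial with uniform replication."""
    missing = {"sample", *FACTORS} - set(design.columns)
    if missing:
        raise ValueError(f"design lacks columns: {sorted(missing)}")
    for f in FACTORS:
        bad = set(design[f]) - set(LEVELS[f])
        if bad:
            raise ValueError(f"unknown {f} levels: {sorted(bad)}")
    counts = design.groupby(list(FACTORS), observed=True).size()
    if len(counts) != 8:
        raise ValueError("design is not full factorial (8 cells required)")
    if counts.nunique() != 1:
        raise ValueError("replicate count must be uniform across cells")
    if counts.iloc[0] < 2:
        raise ValueError("need >= 2 replicates per cell")
    return design


def group_key(row) -> str:
    return f"{row.sex}-{row.genotype}-{row.organ}"


def _group_columns(design: pd.DataFrame) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for row in design.itertuples():
        groups.setdefault(group_key(row), []).append(row.sample)
    return {g: groups[g] for g in sorted(groups)}


def fit_factorial_anova(matrix: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-probe omnibus ANOVA over the 8 cells + group-vs-grand-mean log2FC.

    Returns a frame indexed by probe with ``p_omnibus``, ``q`` (BH across
    probes), ``flag_zero_variance`` and one ``lfc_<group>`` column per cell.
    Probes with zero within-cell variance get an undefined p and a flag.
    """
    design = validate_design(design)
    groups = _group_columns(design)
    X = matrix[design["sample"].tolist()].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("expression matrix must be finite")
    n_probes = X.shape[0]
    g_names = list(groups)
    G = len(g_names)
    r = len(next(iter(groups.values())))
    N = G * r

    means = np.empty((n_probes, G))
    ss_within = np.zeros(n_probes)
    col_idx = {s: i for i, s in enumerate(matrix[design["sample"].tolist()].columns)}
    for gi, g in enumerate(g_names):
        cols = [col_idx[s] for s in groups[g]]
        sub = X[:, cols]
        means[:, gi] = sub.mean(axis=1)
        ss_within += ((sub - means[:, gi][:, None]) ** 2).sum(axis=1)
    grand = X.mean(axis=1)
    ss_between = r * ((means - grand[:, None]) ** 2).sum(axis=1)

    df1, df2 = G - 1, N - G
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df1) / (ss_within / df2)
    zero_var = ss_within == 0
    p = np.where(zero_var, np.nan, stats.f.sf(F, df1, df2))

    q = np.full(n_probes, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        from statsmodels.stats.multitest import multipletests

        q[ok] = multipletests(p[ok], method="fdr_bh")[1]

    out = pd.DataFrame(
        {"p_omnibus": p, "q": q, "flag_zero_variance": zero_var}, index=matrix.index
    )
    for gi, g in enumerate(g_names):
        out[f"lfc_{g}"] = means[:, gi] - grand
    return out


def default_contrasts() -> list[tuple[str, str, str]]:
    """Same-sex, same-organ WT-versus-KO contrasts (label, group_a, group_b)."""
    out = []
    for sex in LEVELS["sex"]:
        for organ in LEVELS["organ"]:
            out.append(
                (f"{sex}-{organ}", f"{sex}-KO-{organ}", f"{sex}-WT-{organ}")
            )
    return out


def posthoc_pairwise(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    contrasts: Sequence[tuple[str, str, str]] | None = None,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per probe x contrast: pairwise log2FC (a - b) and a two-sample t p.

    Welch by default (robust at n = 2-4 per cell); pooled-variance t by flag.
    Long format: probe, contrast, lfc, p_posthoc.
    """
    design = validate_design(design)
    groups = _group_columns(design)
    contrasts = list(contrasts or default_contrasts())
    frames = []
    for label, ga, gb in contrasts:
        A = matrix[groups[ga]].to_numpy(dtype=float)
        B = matrix[groups[gb]].to_numpy(dtype=float)
        t = stats.ttest_ind(A, B, axis=1, equal_var=equal_var)
        frames.append(
            pd.DataFrame(
                {
                    "probe": matrix.index,
                    "contrast": label,
                    "lfc": A.mean(axis=1) - B.mean(axis=1),
                    "p_posthoc": t.pvalue,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def call_differential(
    anova: pd.DataFrame,
    posthoc: pd.DataFrame,
    config: DEConfig | None = None,
) -> pd.DataFrame:
    """Apply the significance + effect-size gates; flags are recomputable
    from the stored statistics and the config alone."""
    config = config or DEConfig()
    lfc_cols = [c for c in anova.columns if c.startswith("lfc_")]
    max_abs_lfc = anova[lfc_cols].abs().max(axis=1)
    multivariate = (anova["q"] < config.fdr_alpha) & (max_abs_lfc > config.snr_lfc)

    df = posthoc.copy()
    df["multivariate_significant"] = df["probe"].map(multivariate).fillna(False)
    df["pairwise_differential"] = (
        df["multivariate_significant"]
        & (df["p_posthoc"] < config.posthoc_alpha)
        & (df["lfc"].abs() > config.practical_lfc)
    )
    df["robust"] = df["pairwise_differential"] & (df["lfc"].abs() > config.snr_lfc)
    df["q"] = df["probe"].map(anova["q"])
    return df


def curate_probes(
    probes: Sequence[str], annotation: pd.DataFrame
) -> tuple[list[str], dict[str, int]]:
    """Keep probes mapping to exactly one non-RIKEN gene symbol.

    ``annotation``: columns probe, genes (semicolon-joined symbols, may be
    empty), riken (bool).  Unannotated probes count as no-gene.  Returns the
    curated probe list plus removal tallies per category.
    """
    ann = annotation.set_index("probe")
    kept: list[str] = []
    removed = {"multi_gene": 0, "no_gene": 0, "riken": 0}
    for p in probes:
        if p not in ann.index:
            removed["no_gene"] += 1
            continue
        genes = [g for g in str(ann.at[p, "genes"] or "").split(";") if g]
        if len(genes) == 0:
            removed["no_gene"] += 1
        elif len(genes) > 1:
            removed["multi_gene"] += 1
        elif bool(ann.at[p, "riken"]):
            removed["riken"] += 1
        else:
            kept.append(p)
    return kept, removed


@dataclass
class PCASummary:
    variance_pct: np.ndarray       # non-increasing, sums to <= 100
    scores: pd.DataFrame           # samples x components
    flag_rank_deficient: bool = False


def pca_on_significant(matrix: pd.DataFrame, n_components: int | None = None) -> PCASummary:
    """Centered PCA of samples over the significant-probe expression matrix.

    Deterministic up to sign; ~zero-variance components are excluded, with a
    flag when the input was rank deficient.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 3:
        raise ValueError("PCA needs >= 2 probes and >= 3 samples")
    from sklearn.decomposition import PCA

    X = matrix.to_numpy(dtype=float).T  # samples x probes
    max_comp = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_components or max_comp, svd_solver="full")
    scores = pca.fit_transform(X - X.mean(axis=0))
    keep = pca.explained_variance_ > 1e-12
    flag = keep.sum() < (n_components or max_comp)
    scores = scores[:, keep]
    var_pct = pca.explained_variance_ratio_[keep] * 100.0
    cols = [f"PC{i+1}" for i in range(scores.shape[1])]
    return PCASummary(
        var_pct, pd.DataFrame(scores, index=matrix.columns, columns=cols), flag
    )


def cluster_patterns(
    lfc_profiles: pd.DataFrame, k: int = 4
) -> tuple[pd.Series, pd.DataFrame]:
    """Cluster probes into expression patterns.

    ``lfc_profiles``: probes x contrast log2FC profiles (e.g. KO-vs-WT per
    sex/organ).  Distance is 1 - Pearson correlation, average linkage, cut
    at ``k`` clusters.  Returns (probe -> cluster label, per-cluster log2FC
    min/max/IQR summary).  Constant profiles have no defined correlation and
    are rejected.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > lfc_profiles.shape[0]:
        raise ValueError("k exceeds probe count")
    X = lfc_profiles.to_numpy(dtype=float)
    if (X.std(axis=1) == 0).any():
        raise ValueError("constant log2FC profiles cannot be correlation-clustered")
    if lfc_profiles.shape[0] == 1 or k == 1:
        labels = pd.Series(1, index=lfc_profiles.index, name="cluster")
    else:
        dist = ssd.pdist(X, metric="correlation")
        link = sch.linkage(dist, method="average")
        labels = pd.Series(
            sch.fcluster(link, t=k, criterion="maxclust"),
            index=lfc_profiles.index,
            name="cluster",
        )
    rows = []
    flat = lfc_profiles.stack()
    for c in sorted(labels.unique()):
        vals = flat[labels[labels == c].index]
        q1, q3 = np.percentile(vals, [25, 75])
        rows.append(
            {
                "cluster": c,
                "n_probes": int((labels == c).sum()),
                "lfc_min": float(vals.min()),
                "lfc_max": float(vals.max()),
                "lfc_iqr_low": float(q1),
                "lfc_iqr_high": float(q3),
            }
        )
    return labels, pd.DataFrame(rows).set_index("cluster")


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Optional utility: make every sample share the mean empirical distribution."""
    ranks = matrix.rank(method="average", axis=0)
    mean_sorted = np.sort(matrix.to_numpy(), axis=0).mean(axis=1)
    return ranks.apply(
        lambda col: np.interp(col, np.arange(1, len(col) + 1), mean_sorted)
    )
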