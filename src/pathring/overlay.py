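"""Transcriptomic overlay: preprocessing, differential testing, map annotation.

The pipeline mirrors a standard two-colour-free microarray workflow for a
two-group design (e.g. 3 cardiac-fibroblast vs 3 tail-fibroblast arrays):

1. average duplicate probes and log2-transform (:func:`preprocess`);
2. quantile-normalise so all arrays share one empirical distribution
   (:func:`quantile_normalize`);
3. test each feature for differential expression with an unpaired two-sample
   t-test — either the ordinary pooled-variance test (:func:`ordinary_t`) or
   the empirical-Bayes moderated test (:func:`moderated_t`), in which each
   feature's sample variance s² (d residual degrees of freedom) is shrunk
   toward a prior s₀² carrying d₀ prior degrees of freedom,

       s̃² = (d₀·s₀² + d·s²) / (d₀ + d),

   the moderated t uses s̃ in place of s and is referred to a t distribution
   on d + d₀ degrees of freedom.  The hyperparameters (d₀, s₀²) are fitted
   to the marginal distribution of the observed variances by matching the
   moments of log s² under the scaled-F marginal (Smyth-style estimation);
4. paint map nodes by log2 fold-change on a red→yellow scale
   (:func:`overlay_map`) and select candidate genes that are both strongly
   differential and anchored in the curated map (:func:`select_candidates`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from pathring.model import EntityClass, PathwayMap, normalize_symbol

__all__ = [
    "ExpressionMatrix",
    "ColorScale",
    "CandidateSet",
    "DEFAULT_OVERLAY_CLASSES",
    "preprocess",
    "minimum_signal_filter",
    "quantile_normalize",
    "ordinary_t",
    "moderated_t",
    "fit_variance_prior",
    "trigamma_inverse",
    "benjamini_hochberg",
    "overlay_map",
    "select_candidates",
    "read_expression_tsv",
    "read_groups_tsv",
    "read_mapping_tsv",
]

#: Node classes a transcript can meaningfully annotate (genes/proteins/receptors);
#: drugs, phenotypes and physiological conditions are excluded from overlays.
DEFAULT_OVERLAY_CLASSES: frozenset[EntityClass] = frozenset(
    {
        EntityClass.RECEPTOR,
        EntityClass.INTRACELLULAR_PROTEIN,
        EntityClass.EXTRACELLULAR_PROTEIN,
        EntityClass.GENE_EXPRESSION,
    }
)


@dataclass
class ExpressionMatrix:
    """A features × samples expression matrix with a two-group design.

    ``values`` is a DataFrame indexed by feature id with sample-id columns;
    ``groups`` maps each sample id to its group label; ``log2_scale`` flags
    whether values are already log2-transformed.
    """

    values: pd.DataFrame
    groups: pd.Series
    log2_scale: bool = False

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.values.columns[self.groups.isna()])
            raise ValueError(f"samples without a group label: {missing}")

    @property
    def group_levels(self) -> list[str]:
        # first-appearance order of the labels fixes the fold-change sign:
        # logFC = mean(level 1) - mean(level 2)
        return list(dict.fromkeys(self.groups))

    def split(self) -> tuple[np.ndarray, np.ndarray]:
        """(group1 values, group2 values) as arrays, features × n_i."""
        levels = self.group_levels
        if len(levels) != 2:
            raise ValueError(f"need exactly two groups, got {levels}")
        g1 = self.values.loc[:, self.groups == levels[0]].to_numpy(float)
        g2 = self.values.loc[:, self.groups == levels[1]].to_numpy(float)
        return g1, g2


def read_expression_tsv(path, groups_path=None) -> ExpressionMatrix | pd.DataFrame:
    """Read a TSV matrix (first column feature id, header sample ids)."""
    values = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if groups_path is None:
        return values
    return ExpressionMatrix(values=values, groups=read_groups_tsv(groups_path))


def read_groups_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "group"], comment="#")
    return pd.Series(df["group"].values, index=df["sample_id"].astype(str))


def read_mapping_tsv(path) -> dict[str, str]:
    """feature_id → entity_id mapping table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["feature_id", "entity_id"], comment="#")
    return dict(zip(df["feature_id"].astype(str), df["entity_id"].astype(str)))


# -- preprocessing ---------------------------------------------------------


def preprocess(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Average duplicate feature rows, then log2-transform.

    Requires linear-scale strictly positive signals.
    """
    if matrix.log2_scale:
        raise ValueError("matrix is already log2-scale")
    bad = matrix.values.index[(matrix.values <= 0).any(axis=1)]
    if len(bad):
        raise ValueError(
            f"non-positive signal for feature(s) {list(bad[:5])!r}; "
            "log2 transform requires positive linear values"
        )
    averaged = matrix.values.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(
        values=np.log2(averaged), groups=matrix.groups, log2_scale=True
    )


def minimum_signal_filter(
    matrix: ExpressionMatrix, threshold: float = 1.0
) -> ExpressionMatrix:
    """Drop features whose linear signal is below ``threshold`` in all samples.

    Emulates an array-QC raw-signal floor applied upstream of normalisation.
    """
    if matrix.log2_scale:
        raise ValueError("minimum-signal filter applies to linear-scale values")
    keep = (matrix.values >= threshold).any(axis=1)
    return ExpressionMatrix(
        values=matrix.values.loc[keep], groups=matrix.groups, log2_scale=False
    )


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the mean empirical distribution.

    Each column's k-th order statistic is replaced by the across-column mean
    of the k-th order statistics; ties within a column receive the mean of
    the values their tied ranks would have taken.  Ranks within each column
    are preserved, all columns end up with identical sorted vectors, and the
    operation is idempotent.
    """
    values = matrix.values
    if values.shape[1] < 2:
        warnings.warn("quantile normalization needs ≥2 samples; returning input")
        return matrix
    arr = values.to_numpy(float)
    mean_sorted = np.sort(arr, axis=0).mean(axis=1)
    n = arr.shape[0]
    out = np.empty_like(arr)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, mean_sorted)
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=values.index, columns=values.columns),
        groups=matrix.groups,
        log2_scale=matrix.log2_scale,
    )


# -- differential testing --------------------------------------------------


def _group_stats(matrix: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray, int, int]:
    g1, g2 = matrix.split()
    n1, n2 = g1.shape[1], g2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(f"both groups need ≥2 samples, got {n1} and {n2}")
    logfc = g1.mean(axis=1) - g2.mean(axis=1)
    # pooled variance with d = n1+n2-2 degrees of freedom
    ss = g1.var(axis=1, ddof=1) * (n1 - 1) + g2.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / (n1 + n2 - 2)
    return logfc, s2, n1, n2


def ordinary_t(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-feature unpaired pooled-variance t-test between the two groups.

    Returns a DataFrame indexed by feature with columns ``log2_fold_change``,
    ``statistic``, ``p_value`` and ``test_kind``.  Features with zero pooled
    variance get NaN statistic and p-value (the test is undefined there).
    """
    logfc, s2, n1, n2 = _group_stats(matrix)
    d = n1 + n2 - 2
    se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, np.where(logfc == 0, 0.0, np.nan))
        t = np.where((se == 0) & (logfc == 0), np.nan, t)
        p = 2.0 * stats.t.sf(np.abs(t), df=d)
    return pd.DataFrame(
        {
            "log2_fold_change": logfc,
            "statistic": t,
            "p_value": p,
            "test_kind": "ordinary_t",
        },
        index=matrix.values.index,
    )


def trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    y = np.asarray(y, dtype=float)
    x = np.where(y > 1e7, 1.0 / np.sqrt(y), 0.5 + 1.0 / y)
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) < 1e-10 * x):
            break
    return x


def fit_variance_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Estimate (d0, s0²) from observed sample variances.

    Under the hierarchical model, s² is marginally s0²·F(d, d0); matching the
    mean and variance of log s² (via digamma/trigamma moments of log-F)
    yields closed-form estimates.  Returns ``d0 = inf`` when the observed
    log-variance spread is no larger than pure chi-square sampling noise.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        raise ValueError("too few positive variances to fit a prior")
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1)
    resid = evar - special.polygamma(1, d / 2.0)
    if resid <= 0:
        # no excess spread beyond chi-square noise: variances look common,
        # so the prior is infinitely informative and s0² is the plain mean
        return float("inf"), float(s2.mean())
    d0 = 2.0 * float(trigamma_inverse(np.array(resid)))
    s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderated_t(
    matrix: ExpressionMatrix, min_features: int = 10
) -> pd.DataFrame:
    """Empirical-Bayes moderated t-test between the two groups.

    Falls back to :func:`ordinary_t` (with a warning) when the prior cannot
    be estimated, e.g. with fewer than ``min_features`` usable variances.
    The returned DataFrame carries ``d0`` and ``s0_2`` in ``df.attrs``.
    """
    logfc, s2, n1, n2 = _group_stats(matrix)
    d = n1 + n2 - 2
    usable = np.isfinite(s2) & (s2 > 0)
    if usable.sum() < min_features:
        warnings.warn(
            f"only {int(usable.sum())} usable variances (<{min_features}); "
            "falling back to the ordinary t-test"
        )
        return ordinary_t(matrix)
    try:
        d0, s0_2 = fit_variance_prior(s2[usable], d)
    except (ValueError, FloatingPointError) as exc:  # pragma: no cover
        warnings.warn(f"variance-prior estimation failed ({exc}); using ordinary t")
        return ordinary_t(matrix)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        df_total = d + d0
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / se
        p = (
            2.0 * stats.norm.sf(np.abs(t))
            if np.isinf(df_total)
            else 2.0 * stats.t.sf(np.abs(t), df=df_total)
        )
    out = pd.DataFrame(
        {
            "log2_fold_change": logfc,
            "statistic": t,
            "p_value": p,
            "test_kind": "moderated_t",
        },
        index=matrix.values.index,
    )
    out.attrs["d0"] = d0
    out.attrs["s0_2"] = s0_2
    out.attrs["df_residual"] = d
    return out


def benjamini_hochberg(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """BH-adjusted p-values (step-up FDR); optional, off by default downstream."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


# -- map annotation and candidate selection --------------------------------


@dataclass(frozen=True)
class ColorScale:
    """Monotone red→yellow scale over a symmetric log-fold-change domain.

    Minimum of the domain maps to yellow, the maximum to red, zero to the
    midpoint orange; values outside the domain clamp to the endpoints.
    """

    vmin: float
    vmax: float
    low_rgb: tuple[float, float, float] = (1.0, 1.0, 0.0)  # yellow
    high_rgb: tuple[float, float, float] = (1.0, 0.0, 0.0)  # red

    @classmethod
    def symmetric(cls, logfc: np.ndarray | pd.Series) -> "ColorScale":
        m = float(np.nanmax(np.abs(np.asarray(logfc, dtype=float)))) or 1.0
        return cls(vmin=-m, vmax=m)

    def __call__(self, value: float) -> str:
        span = self.vmax - self.vmin
        frac = 0.5 if span == 0 else (np.clip(value, self.vmin, self.vmax) - self.vmin) / span
        rgb = tuple(
            lo + frac * (hi - lo) for lo, hi in zip(self.low_rgb, self.high_rgb)
        )
        return "#{:02x}{:02x}{:02x}".format(*(int(round(255 * c)) for c in rgb))


def _resolve_mapping(
    pmap: PathwayMap, features, mapping: dict[str, str] | None
) -> dict[str, str]:
    """feature id → entity id, via an explicit table or direct symbol match."""
    resolved: dict[str, str] = {}
    for feat in features:
        target = mapping.get(str(feat), feat) if mapping else feat
        eid = normalize_symbol(str(target))
        if eid in pmap.entities:
            resolved[str(feat)] = eid
    return resolved


def overlay_map(
    pmap: PathwayMap,
    diff: pd.DataFrame,
    scale: ColorScale | None = None,
    mapping: dict[str, str] | None = None,
    classes: frozenset[EntityClass] = DEFAULT_OVERLAY_CLASSES,
) -> dict[str, dict]:
    """Annotate matched gene/protein/receptor entities with logFC and colour.

    Returns entity id → {"log2_fold_change", "p_value", "color", "feature_id"}
    for entities of the allowed classes; other classes are never annotated
    even when a feature symbol collides with them.  Emits a warning and an
    empty annotation dict when nothing matches.
    """
    resolved = _resolve_mapping(pmap, diff.index, mapping)
    if scale is None:
        scale = ColorScale.symmetric(diff["log2_fold_change"])
    annotations: dict[str, dict] = {}
    for feat, eid in resolved.items():
        if pmap.entities[eid].entity_class not in classes:
            continue
        row = diff.loc[feat]
        annotations[eid] = {
            "feature_id": feat,
            "log2_fold_change": float(row["log2_fold_change"]),
            "p_value": float(row["p_value"]),
            "color": scale(float(row["log2_fold_change"])),
        }
    if not annotations:
        warnings.warn("no differential feature matched an overlayable map entity")
    return annotations


@dataclass(frozen=True)
class CandidateSet:
    """Map-anchored differential genes passing both thresholds."""

    genes: tuple[str, ...]
    p_threshold: float
    abs_logfc_threshold: float
    allowed_classes: frozenset[EntityClass]
    table: pd.DataFrame = field(compare=False, default=None, repr=False)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


def select_candidates(
    pmap: PathwayMap,
    diff: pd.DataFrame,
    p_threshold: float = 0.05,
    abs_logfc_threshold: float = 2.0,
    allowed_classes: frozenset[EntityClass] = DEFAULT_OVERLAY_CLASSES,
    mapping: dict[str, str] | None = None,
    adjust: bool = False,
) -> CandidateSet:
    """Select genes that are strongly differential AND present in the map.

    A feature qualifies when p < ``p_threshold``, |logFC| >
    ``abs_logfc_threshold``, and its symbol (or explicit mapping) resolves to
    a map entity of an allowed class.  ``adjust=True`` applies
    Benjamini–Hochberg to the p-values first (off by default: raw-p
    thresholds are the conventional choice for this workflow).  Candidates
    are sorted by |logFC| descending.
    """
    if p_threshold <= 0 or abs_logfc_threshold <= 0:
        raise ValueError("thresholds must be positive")
    p = benjamini_hochberg(diff["p_value"]) if adjust else diff["p_value"].to_numpy()
    passes = (p < p_threshold) & (
        diff["log2_fold_change"].abs().to_numpy() > abs_logfc_threshold
    )
    resolved = _resolve_mapping(pmap, diff.index[passes], mapping)
    rows = []
    for feat, eid in resolved.items():
        if pmap.entities[eid].entity_class not in allowed_classes:
            continue
        row = diff.loc[feat]
        rows.append(
            {
                "gene": feat,
                "entity_id": eid,
                "log2_fold_change": float(row["log2_fold_change"]),
                "p_value": float(row["p_value"]),
            }
        )
    table = pd.DataFrame(
        rows, columns=["gene", "entity_id", "log2_fold_change", "p_value"]
    )
    table = table.reindex(
        table["log2_fold_change"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)
    return CandidateSet(
        genes=tuple(table["gene"]),
        p_threshold=p_threshold,
        abs_logfc_threshold=abs_logfc_threshold,
        allowed_classes=allowed_classes,
        table=table,
    )
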