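"""Composition arithmetic and multivariate statistics.

Covers digestibility and relative-phenolics arithmetic on the per-line
composition table, summary statistics (the coefficient of variation uses
the population standard deviation, divisor n, which is what reproduces
the published summary values), PCA with correlation-circle loadings,
one- and two-way ANOVA with Tukey multiple comparisons, and channel-wise
correlation profiles between tissue pseudospectra and relative phenolic
amounts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .channels import CANONICAL_CHANNELS


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# composition arithmetic
# ---------------------------------------------------------------------------

def ivcwd(M1_g: float, M2_g: float) -> float:
    """In vitro cell wall digestibility: mass fraction degraded, percent."""
    if M1_g <= 0:
        raise StatsError("M1 must be positive")
    if not 0 <= M2_g <= M1_g:
        raise StatsError("M2 must lie in [0, M1]")
    return (M1_g - M2_g) / M1_g * 100.0


@dataclass(frozen=True)
class RelativePhenolics:
    kl_rel: float
    pca_rel: float
    fa_rel: float

    def __post_init__(self) -> None:
        total = self.kl_rel + self.pca_rel + self.fa_rel
        if abs(total - 100.0) > 1e-6:
            raise StatsError(f"relative phenolics sum to {total}, not 100")


def relative_phenolics(kl: float, pca: float, fa: float) -> RelativePhenolics:
    """Each phenolic as a percentage of the KL + pCA + FA sum."""
    if min(kl, pca, fa) < 0:
        raise StatsError("phenolic contents must be non-negative")
    total = kl + pca + fa
    if total <= 0:
        raise StatsError("phenolic sum is zero")
    return RelativePhenolics(kl / total * 100.0, pca / total * 100.0, fa / total * 100.0)


def summary_stats(values: Sequence[float]) -> tuple[float, float]:
    """Mean and coefficient of variation (population sd, divisor n), percent."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise StatsError("need at least two values")
    mean = float(arr.mean())
    if mean == 0:
        raise StatsError("CV undefined for zero mean")
    return mean, float(arr.std(ddof=0) / mean * 100.0)


def load_composition_table(path=None) -> pd.DataFrame:
    """Load a composition table; defaults to the packaged 14-line reference.

    Adds relative-phenolics columns (``kl_rel``, ``pca_rel``, ``fa_rel``).
    """
    if path is None:
        with resources.files("stemhisto.data").joinpath("composition_14lines.csv").open() as f:
            df = pd.read_csv(f)
    else:
        df = pd.read_csv(path)
    required = {"line_id", "klason_lignin_pct_cw", "ester_pca_pct_cw", "ester_fa_pct_cw"}
    missing = required - set(df.columns)
    if missing:
        raise StatsError(f"composition table missing columns {sorted(missing)}")
    total = df["klason_lignin_pct_cw"] + df["ester_pca_pct_cw"] + df["ester_fa_pct_cw"]
    df["kl_rel"] = df["klason_lignin_pct_cw"] / total * 100.0
    df["pca_rel"] = df["ester_pca_pct_cw"] / total * 100.0
    df["fa_rel"] = df["ester_fa_pct_cw"] / total * 100.0
    return df


def load_reference_cell_sizes() -> pd.DataFrame:
    """Packaged grey-level mean cell sizes for the four reference lines."""
    with resources.files("stemhisto.data").joinpath("cell_sizes_4lines.csv").open() as f:
        return pd.read_csv(f)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # variables x components (orthonormal)
    var_explained_pct: np.ndarray
    standardized: bool
    mean_: np.ndarray
    scale_: np.ndarray

    def correlation_circle(self) -> pd.DataFrame:
        """Correlation of each original variable with each component score."""
        eigen = self.var_explained_pct / 100.0 * (self.scores.shape[0] > 1)
        # direct Pearson correlations are robust to the scaling convention
        data = {}
        for comp in self.scores.columns:
            data[comp] = [
                np.corrcoef(self._original[:, j], self.scores[comp])[0, 1]
                for j in range(self.loadings.shape[0])
            ]
        return pd.DataFrame(data, index=self.loadings.index)


def pca(table: pd.DataFrame, standardize: bool = True,
        n_components: int | None = None) -> PcaResult:
    """Principal component analysis by SVD of the centred (scaled) matrix.

    ``standardize=True`` divides each variable by its standard deviation
    (required when variables have different units); pseudospectra are
    analysed unstandardised so that baseline channels keep their small
    weight.
    """
    X = table.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise StatsError("missing values in PCA input")
    n, p = X.shape
    if n < 2:
        raise StatsError("need at least two samples")
    mean = X.mean(axis=0)
    Xc = X - mean
    if standardize:
        scale = X.std(axis=0, ddof=1)
        if np.any(scale == 0):
            const = [str(c) for c, s in zip(table.columns, scale) if s == 0]
            raise StatsError(f"constant variables under standardization: {const}")
        Xc = Xc / scale
    else:
        scale = np.ones(p)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n - 1, p) if n_components is None else min(n_components, min(n - 1, p))
    comps = [f"PC{i+1}" for i in range(k)]
    scores = pd.DataFrame(U[:, :k] * s[:k], index=table.index, columns=comps)
    loadings = pd.DataFrame(Vt[:k].T, index=table.columns, columns=comps)
    var = s ** 2
    result = PcaResult(scores=scores, loadings=loadings,
                       var_explained_pct=var[:k] / var.sum() * 100.0,
                       standardized=standardize, mean_=mean, scale_=scale)
    result._original = Xc * scale + 0.0  # centred/scaled design for circle corr
    return result


# ---------------------------------------------------------------------------
# ANOVA and multiple comparisons
# ---------------------------------------------------------------------------

def anova(df: pd.DataFrame, response: str, factors: Sequence[str]) -> pd.DataFrame:
    """One- or two-way ANOVA (Type II sums of squares, with interaction).

    Returns the ANOVA table with an added significance code column
    (``***`` p<0.001, ``**`` p<0.01, ``*`` p<0.05).
    """
    factors = list(factors)
    if not 1 <= len(factors) <= 2:
        raise StatsError("one or two factors supported")
    for f in factors:
        if df[f].nunique() < 2:
            raise StatsError(f"factor {f!r} has fewer than two levels")
    terms = " * ".join(f"C({f})" for f in factors)
    model = smf.ols(f"{response} ~ {terms}", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)

    def stars(p: float) -> str:
        if np.isnan(p):
            return ""
        return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else "ns"

    table["signif"] = [stars(p) for p in table["PR(>F)"]]
    return table


def _compact_letters(levels: Sequence[str],
                     different: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display by the insert-and-absorb algorithm.

    Levels sharing a letter are not significantly different; each
    significant pair ends up in no common group.
    """
    groups: list[set[str]] = [set(levels)]
    for a, b in sorted(different):
        split: list[set[str]] = []
        for g in groups:
            if a in g and b in g:
                split.extend([g - {a}, g - {b}])
            else:
                split.append(g)
        # drop duplicates and groups absorbed by a superset
        groups = []
        for g in split:
            if g and not any(g < h for h in split) and g not in groups:
                groups.append(g)
    letters = {lv: "" for lv in levels}
    for letter, g in zip("abcdefghijklmnopqrstuvwxyz", groups):
        for lv in sorted(g):
            letters[lv] += letter
    return letters


def emm_compare(df: pd.DataFrame, response: str, factor: str,
                alpha: float = 0.05) -> tuple[pd.DataFrame, dict[str, str]]:
    """Tukey HSD pairwise comparison of factor-level means + letter display."""
    tk = pairwise_tukeyhsd(df[response], df[factor], alpha=alpha)
    res = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    res["p-adj"] = res["p-adj"].astype(float)
    different = {(str(r["group1"]), str(r["group2"]))
                 for _, r in res.iterrows() if bool(r["reject"])}
    levels = sorted(df[factor].astype(str).unique())
    return res, _compact_letters(levels, different)


# ---------------------------------------------------------------------------
# correlation profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationProfile:
    tissue: str
    compound: str
    r_per_channel: tuple[float, ...]
    p_per_channel: tuple[float, ...]
    significant: tuple[bool, ...]


def correlation_profile(spectra: pd.DataFrame, rel_phenolics: pd.DataFrame,
                        compounds: Sequence[str] = ("kl_rel", "pca_rel", "fa_rel"),
                        alpha: float = 0.05) -> list[CorrelationProfile]:
    """Pearson correlation of each channel with each relative compound.

    ``spectra`` is long over lines and tissues with the 11 channel columns;
    ``rel_phenolics`` has ``line_id`` plus the compound columns.  P-values
    are two-sided and unadjusted (one point per channel in the display).
    """
    merged = spectra.merge(rel_phenolics, on="line_id", how="inner")
    profiles = []
    for tissue, sub in merged.groupby("tissue"):
        if sub["line_id"].nunique() < 4:
            raise StatsError(f"insufficient-data: fewer than 4 matched lines for {tissue}")
        for compound in compounds:
            rs, ps = [], []
            for ch in CANONICAL_CHANNELS:
                r, p = sps.pearsonr(sub[ch], sub[compound])
                rs.append(float(r))
                ps.append(float(p))
            profiles.append(CorrelationProfile(
                tissue=str(tissue), compound=compound,
                r_per_channel=tuple(rs), p_per_channel=tuple(ps),
                significant=tuple(p < alpha for p in ps)))
    return profiles


def phenolic_intercorrelations(composition: pd.DataFrame) -> dict[str, float]:
    """Pairwise Pearson correlations among the relative phenolic amounts."""
    out = {}
    for a, b in itertools.combinations(("kl_rel", "pca_rel", "fa_rel"), 2):
        out[f"{a}~{b}"] = float(np.corrcoef(composition[a], composition[b])[0, 1])
    return out
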