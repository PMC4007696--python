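"""Root-growth traits, CRD analysis of variance and genetic parameters.

Aluminum tolerance in nutrient-solution assays is scored by root growth:
net root growth NRG = FRL - IRL (final minus initial root length, cm)
under control and Al treatments, and relative net root growth
RNRG = 100 x NRG_Al / NRG_c (percent), which removes intrinsic root-growth
differences unrelated to Al tolerance.  A one-way ANOVA on plot values
from a completely randomized design yields mean squares from which the
family-mean heritability h2 = (MSG - MSE) / MSG, the genetic variance
s2g = (MSG - MSE) / r, and the coefficients of experimental and genetic
variation CVe = 100 sqrt(MSE) / mean, CVg = 100 sqrt(s2g) / mean follow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeTable",
    "AnovaResult",
    "TraitSummary",
    "net_root_growth",
    "relative_net_root_growth",
    "plot_traits",
    "line_traits",
    "anova_crd",
    "trait_summary",
]

TREATMENTS = ("control", "Al")


@dataclass
class PhenotypeTable:
    """Plot-level phenotype records: line, rep, treatment, IRL, FRL (cm).

    (line, rep, treatment) combinations are unique; root lengths are
    non-negative.  ``causal_markers`` is populated by the simulator when
    the table is synthetic.
    """

    data: pd.DataFrame
    causal_markers: pd.DataFrame | None = field(default=None, compare=False)

    REQUIRED = ("line", "rep", "treatment", "irl", "frl")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        df = self.data
        if (df["irl"] < 0).any() or (df["frl"] < 0).any():
            raise ValueError("root lengths must be non-negative")
        if df.duplicated(subset=["line", "rep", "treatment"]).any():
            raise ValueError("(line, rep, treatment) must be unique")
        bad = set(df["treatment"]) - set(TREATMENTS)
        if bad:
            raise ValueError(f"unknown treatments: {sorted(bad)}")

    @classmethod
    def read_csv(cls, path) -> "PhenotypeTable":
        return cls(pd.read_csv(path, comment="#"))

    def to_csv(self, path, **kwargs) -> None:
        self.data.to_csv(path, index=False, **kwargs)


def net_root_growth(frl, irl):
    """NRG = FRL - IRL (cm); negative growth is allowed but warned about."""
    nrg = np.asarray(frl, dtype=float) - np.asarray(irl, dtype=float)
    if (nrg < 0).any():
        warnings.warn("negative net root growth encountered (FRL < IRL)")
    return nrg if nrg.ndim else float(nrg)


def relative_net_root_growth(nrg_al, nrg_c):
    """RNRG = 100 x NRG_Al / NRG_c (percent).

    Records with non-positive control growth are undefined: they come back
    as NaN (flagged for exclusion) with a warning.
    """
    nrg_al = np.asarray(nrg_al, dtype=float)
    nrg_c = np.asarray(nrg_c, dtype=float)
    bad = nrg_c <= 0
    if bad.any():
        warnings.warn(
            f"{int(np.sum(bad))} record(s) with non-positive control NRG flagged (RNRG undefined)"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        rnrg = np.where(bad, np.nan, 100.0 * nrg_al / np.where(bad, 1.0, nrg_c))
    return rnrg if rnrg.ndim else float(rnrg)


def plot_traits(table: PhenotypeTable) -> pd.DataFrame:
    """Per-(line, rep) NRG_c, NRG_Al and RNRG % from plot records."""
    df = table.data.copy()
    df["nrg"] = net_root_growth(df["frl"].to_numpy(), df["irl"].to_numpy())
    wide = df.pivot_table(index=["line", "rep"], columns="treatment", values="nrg")
    wide = wide.rename(columns={"control": "nrg_c", "Al": "nrg_al"}).reset_index()
    wide.columns.name = None
    if "nrg_c" not in wide or "nrg_al" not in wide:
        raise ValueError("both control and Al plots are required to compute RNRG")
    wide["rnrg"] = relative_net_root_growth(wide["nrg_al"].to_numpy(), wide["nrg_c"].to_numpy())
    return wide


def line_traits(table: PhenotypeTable) -> pd.DataFrame:
    """Line-level trait means (NRG_c, NRG_Al, RNRG %) across replicates."""
    per_plot = plot_traits(table)
    return (
        per_plot.groupby("line", sort=True)[["nrg_c", "nrg_al", "rnrg"]]
        .mean()
        .reset_index()
    )


@dataclass
class AnovaResult:
    """One-way CRD ANOVA: genotypes vs residual, on plot values."""

    df_genotypes: int
    df_residual: int
    ms_genotypes: float
    ms_residual: float
    f_value: float
    p_value: float
    grand_mean: float
    replicates: int

    @property
    def df_total(self) -> int:
        return self.df_genotypes + self.df_residual

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": ["Genotypes", "Residual", "Total"],
                "df": [self.df_genotypes, self.df_residual, self.df_total],
                "ms": [self.ms_genotypes, self.ms_residual, np.nan],
                "F": [self.f_value, np.nan, np.nan],
                "p": [self.p_value, np.nan, np.nan],
            }
        )


def anova_crd(values: pd.DataFrame, value_col: str = "value") -> AnovaResult:
    """One-way ANOVA of plot values on genotype (completely randomized design).

    ``values`` needs columns ``line`` and ``value_col`` with one row per
    plot.  Lines represented by a single plot are excluded (no
    within-line df) with a warning; the design may be unbalanced, in which
    case Type-I sums of squares on the line factor are used.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = values[["line", value_col]].dropna().rename(columns={value_col: "value"})
    counts = df["line"].value_counts()
    singletons = counts[counts < 2].index
    if len(singletons):
        warnings.warn(
            f"excluding {len(singletons)} line(s) with a single plot from the ANOVA"
        )
        df = df[~df["line"].isin(singletons)]
    g = df["line"].nunique()
    if g < 2:
        raise ValueError("ANOVA needs at least 2 lines with >=2 plots each")
    fit = smf.ols("value ~ C(line)", data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=1)
    ms_g = float(tab.loc["C(line)", "mean_sq"])
    ms_e = float(tab.loc["Residual", "mean_sq"])
    df_g = int(tab.loc["C(line)", "df"])
    df_e = int(tab.loc["Residual", "df"])
    f_val = float(tab.loc["C(line)", "F"])
    p_val = float(tab.loc["C(line)", "PR(>F)"])
    r = int(round(len(df) / g))
    return AnovaResult(
        df_genotypes=df_g,
        df_residual=df_e,
        ms_genotypes=ms_g,
        ms_residual=ms_e,
        f_value=f_val,
        p_value=p_val,
        grand_mean=float(df["value"].mean()),
        replicates=r,
    )


@dataclass
class TraitSummary:
    """Genetic parameters from an ANOVA: h2, CVe %, CVg %, CVg/CVe."""

    h2: float
    cve: float
    cvg: float
    cvg_cve_ratio: float
    sigma2_g: float
    sigma2_e: float

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "h2": self.h2,
                "cve_pct": self.cve,
                "cvg_pct": self.cvg,
                "cvg_cve": self.cvg_cve_ratio,
                "sigma2_g": self.sigma2_g,
                "sigma2_e": self.sigma2_e,
            }
        )


def trait_summary(anova: AnovaResult) -> TraitSummary:
    """Heritability and coefficients of variation from ANOVA mean squares.

    s2g = (MSG - MSE) / r; family-mean h2 = (MSG - MSE) / MSG, truncated
    to [0, 1]; CVe = 100 sqrt(MSE) / grand mean; CVg = 100 sqrt(s2g) /
    grand mean; ratio = CVg / CVe (infinite when MSE = 0).
    """
    msg, mse, r = anova.ms_genotypes, anova.ms_residual, anova.replicates
    if msg < mse:
        warnings.warn("MSG < MSE: heritability truncated to 0")
    s2g = max(0.0, (msg - mse) / r)
    s2e = mse
    h2 = 0.0 if msg <= 0 else min(1.0, max(0.0, (msg - mse) / msg))
    mean = anova.grand_mean
    if mean <= 0:
        raise ValueError("grand mean must be positive for coefficients of variation")
    cve = 100.0 * np.sqrt(mse) / mean
    cvg = 100.0 * np.sqrt(s2g) / mean
    ratio = np.inf if cve == 0 else cvg / cve
    return TraitSummary(
        h2=float(h2),
        cve=float(cve),
        cvg=float(cvg),
        cvg_cve_ratio=float(ratio),
        sigma2_g=float(s2g),
        sigma2_e=float(s2e),
    )
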