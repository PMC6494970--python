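"""Trial-level mixed and linear models.

Three fitted-model surfaces over the variance-component engine:

* :class:`BlocCorrectionModel` — mixed model with fixed year/scenario/check
  effects and random RIL, bloc, RIL x year and RIL x scenario effects; its
  results carry the bloc BLUPs that are subtracted from every plot value to
  remove field-bloc environment ("corrected" data).
* :class:`TraitVarianceModel` — REML decomposition of corrected RIL data into
  genetic, G x year, G x scenario and residual variances, from which
  broad-sense heritability is computed.
* :func:`lsmeans` — fixed-effects least-square line means, jointly over both
  irrigation scenarios or per scenario.

plus :func:`anova_r2_table`, the sequential (type-I) percent-of-sum-of-squares
decomposition used for per-factor r2 reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.formula.api import ols

from .lmm import MixedLMM, RandomFactor

__all__ = [
    "BlocCorrectionModel",
    "BlocCorrectionResults",
    "TraitVarianceModel",
    "TraitVarianceResults",
    "VarianceComponents",
    "broad_sense_heritability",
    "LsMeans",
    "lsmeans",
    "anova_r2_table",
    "IdentifiabilityError",
    "validate_phenotypes",
]

SCENARIOS = ("I", "NI")


class IdentifiabilityError(ValueError):
    """The requested variance decomposition is not estimable from the design."""


def validate_phenotypes(table: pd.DataFrame, trait: str | None = None) -> None:
    required = {"line", "year", "scenario", "bloc", "is_check"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns {sorted(missing)}")
    bad = set(table["scenario"].unique()) - set(SCENARIOS)
    if bad:
        raise ValueError(f"unknown scenario codes {sorted(bad)}; expected I/NI")
    if trait is not None and trait not in table.columns:
        raise ValueError(f"trait column {trait!r} not in phenotype table")


def _fixed_design(df: pd.DataFrame, with_checks: bool):
    """Intercept + year + scenario + year x scenario (+ one column per check
    line).  Treatment coding against the first year / the I scenario."""
    parts = [pd.Series(1.0, index=df.index, name="intercept")]
    years = sorted(df["year"].unique())
    for y in years[1:]:
        parts.append(pd.Series((df["year"] == y).astype(float), name=f"year[{y}]"))
    scens = [s for s in SCENARIOS if s in set(df["scenario"])]
    for s in scens[1:]:
        parts.append(pd.Series((df["scenario"] == s).astype(float),
                               name=f"scenario[{s}]"))
    for y in years[1:]:
        for s in scens[1:]:
            parts.append(pd.Series(
                ((df["year"] == y) & (df["scenario"] == s)).astype(float),
                name=f"year[{y}]:scenario[{s}]"))
    if with_checks:
        for chk in sorted(df.loc[df["is_check"], "line"].unique()):
            parts.append(pd.Series(
                ((df["line"] == chk) & df["is_check"]).astype(float),
                name=f"check[{chk}]"))
    X = pd.concat(parts, axis=1)
    return X.to_numpy(), list(X.columns)


# ----------------------------------------------------------------------
class BlocCorrectionModel:
    """Mixed model for removing field-bloc effects from plot values.

    Fixed: intercept, year, scenario, year x scenario, and one mean shift per
    replicated check line.  Random: RIL genetic effect, bloc within
    (year, scenario), RIL x year, RIL x scenario.  The corrected value of a
    plot is its raw value minus the BLUP of its bloc.
    """

    def __init__(self, table: pd.DataFrame, trait: str):
        validate_phenotypes(table, trait)
        self.table = table.reset_index(drop=True)
        self.trait = trait
        blocs = self.table[["year", "scenario", "bloc"]].drop_duplicates()
        if len(blocs) < 2:
            raise ValueError("bloc correction needs at least 2 blocs")

    @classmethod
    def from_dataframe(cls, table, trait):
        return cls(table, trait)

    def fit(self, reml: bool = True) -> "BlocCorrectionResults":
        df = self.table.dropna(subset=[self.trait])
        y = df[self.trait].to_numpy(dtype=float)
        has_checks = bool(df["is_check"].any())
        X, names = _fixed_design(df, with_checks=has_checks)

        ril_line = df["line"].where(~df["is_check"])
        bloc_key = (df["year"].astype(str) + "/" + df["scenario"].astype(str)
                    + "/" + df["bloc"].astype(str))
        gy_key = (ril_line + "@" + df["year"].astype(str)).where(~df["is_check"])
        ge_key = (ril_line + "@" + df["scenario"].astype(str)).where(~df["is_check"])

        factors = [
            RandomFactor.from_labels("genetic", ril_line),
            RandomFactor.from_labels("bloc", bloc_key),
            RandomFactor.from_labels("g_x_year", gy_key),
            RandomFactor.from_labels("g_x_scenario", ge_key),
        ]
        if df["year"].nunique() < 2:
            factors = [f for f in factors if f.name != "g_x_year"]
        if df["scenario"].nunique() < 2:
            factors = [f for f in factors if f.name != "g_x_scenario"]
        fit = MixedLMM(y, X, factors, exog_names=names).fit(reml=reml)
        blups = fit.blups["bloc"]
        idx = pd.MultiIndex.from_tuples(
            [tuple(k.split("/")) for k in blups.index],
            names=["year", "scenario", "bloc"])
        bloc_blups = pd.Series(blups.to_numpy(), index=idx, name="bloc_blup")
        return BlocCorrectionResults(model=self, lmm=fit, bloc_blups=bloc_blups)


@dataclass
class BlocCorrectionResults:
    model: BlocCorrectionModel
    lmm: object
    bloc_blups: pd.Series

    def corrected(self) -> pd.DataFrame:
        """Input table with the trait column replaced by raw minus bloc BLUP.

        Row count, ordering and all key columns are preserved; plots with a
        missing trait value stay missing."""
        t = self.model.table.copy()
        key = list(zip(t["year"].astype(str), t["scenario"].astype(str),
                       t["bloc"].astype(str)))
        adj = self.bloc_blups.reindex(key).to_numpy()
        adj = np.where(np.isnan(adj), 0.0, adj)  # blocs unseen in the fit
        t[self.model.trait] = t[self.model.trait] - adj
        return t

    def summary(self) -> str:
        head = (f"Bloc-BLUP correction for trait {self.model.trait!r}: "
                f"{len(self.bloc_blups)} blocs, "
                f"sigma2_bloc = {self.lmm.vcomp.get('bloc', 0.0):.6g}")
        return head + "\n\n" + self.lmm.summary()


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class VarianceComponents:
    """REML variance components of corrected RIL data plus design counts."""

    sigma2_g: float
    sigma2_gy: float
    sigma2_ge: float
    sigma2_E: float
    k: int                 # irrigation scenarios
    j: int                 # years
    obs_per_line: float    # obs / i

    def __post_init__(self):
        if min(self.sigma2_g, self.sigma2_gy, self.sigma2_ge, self.sigma2_E) < 0:
            raise ValueError("variance components must be non-negative")
        if self.k < 1 or self.j < 1 or self.obs_per_line <= 0:
            raise ValueError("invalid design counts")


def broad_sense_heritability(vc: VarianceComponents) -> float:
    """h2 = sigma2_g / (sigma2_g + sigma2_ge/k + sigma2_gy/j + sigma2_E/(obs/i))."""
    denom = (vc.sigma2_g + vc.sigma2_ge / vc.k + vc.sigma2_gy / vc.j
             + vc.sigma2_E / vc.obs_per_line)
    if denom <= 0:
        raise ValueError("heritability undefined: all variance components are zero")
    return vc.sigma2_g / denom


class TraitVarianceModel:
    """REML decomposition of corrected RIL phenotypes.

    Fixed: year, scenario, year x scenario.  Random: line, line x year,
    line x scenario; the leftover is residual.  Checks are excluded.
    """

    def __init__(self, corrected: pd.DataFrame, trait: str):
        validate_phenotypes(corrected, trait)
        df = corrected.loc[~corrected["is_check"]].dropna(subset=[trait])
        df = df.reset_index(drop=True)
        if df["line"].nunique() < 2:
            raise ValueError("need >= 2 RIL lines")
        if df["year"].nunique() < 2 and df["scenario"].nunique() < 2:
            cell = df.groupby(["line", "year", "scenario"]).size()
            if (cell <= 1).all():
                raise IdentifiabilityError(
                    "one year, one scenario and no replication: genetic and "
                    "residual variances are confounded")
        self.data = df
        self.trait = trait

    @classmethod
    def from_dataframe(cls, corrected, trait):
        return cls(corrected, trait)

    def fit(self, reml: bool = True) -> "TraitVarianceResults":
        df = self.data
        y = df[self.trait].to_numpy(dtype=float)
        X, names = _fixed_design(df, with_checks=False)
        factors = [RandomFactor.from_labels("genetic", df["line"])]
        if df["year"].nunique() >= 2:
            factors.append(RandomFactor.from_labels(
                "g_x_year", df["line"] + "@" + df["year"].astype(str)))
        if df["scenario"].nunique() >= 2:
            factors.append(RandomFactor.from_labels(
                "g_x_scenario", df["line"] + "@" + df["scenario"].astype(str)))
        fit = MixedLMM(y, X, factors, exog_names=names).fit(reml=reml)
        vc = VarianceComponents(
            sigma2_g=fit.vcomp.get("genetic", 0.0),
            sigma2_gy=fit.vcomp.get("g_x_year", 0.0),
            sigma2_ge=fit.vcomp.get("g_x_scenario", 0.0),
            sigma2_E=fit.sigma2_resid,
            k=int(df["scenario"].nunique()),
            j=int(df["year"].nunique()),
            obs_per_line=float(len(df) / df["line"].nunique()),
        )
        return TraitVarianceResults(model=self, lmm=fit, components=vc)


@dataclass
class TraitVarianceResults:
    model: TraitVarianceModel
    lmm: object
    components: VarianceComponents

    def heritability(self) -> float:
        return broad_sense_heritability(self.components)

    def summary(self) -> str:
        vc = self.components
        lines = [
            f"Variance decomposition for trait {self.model.trait!r} "
            f"({vc.j} years x {vc.k} scenarios, obs/line = {vc.obs_per_line:.2f})",
            f"  sigma2_g  = {vc.sigma2_g:.6g}",
            f"  sigma2_gy = {vc.sigma2_gy:.6g}",
            f"  sigma2_ge = {vc.sigma2_ge:.6g}",
            f"  sigma2_E  = {vc.sigma2_E:.6g}",
            f"  h2        = {self.heritability():.4f}",
        ]
        return "\n".join(lines)


# ----------------------------------------------------------------------
@dataclass
class LsMeans:
    """Per-line adjusted means with the scope they were computed under."""

    values: pd.Series      # index = line
    scope: str             # "all", "I" or "NI"
    dropped_lines: tuple = ()

    def __post_init__(self):
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("non-finite ls-mean")


def lsmeans(corrected: pd.DataFrame, trait: str, scope: str = "all") -> LsMeans:
    """Least-square line means on corrected RIL data.

    scope="all" adjusts for year, scenario and their interaction jointly;
    scope="I"/"NI" subsets to one scenario and adjusts for year only.  Each
    ls-mean is the model prediction for the line averaged over the full
    reference grid of adjustment factors, so on a balanced design it equals
    the line's arithmetic mean.
    """
    validate_phenotypes(corrected, trait)
    if scope not in ("all", "I", "NI"):
        raise ValueError("scope must be 'all', 'I' or 'NI'")
    df = corrected.loc[~corrected["is_check"]].dropna(subset=[trait])
    all_lines = tuple(pd.unique(df["line"]))
    if scope in SCENARIOS:
        df = df[df["scenario"] == scope]
    elif df["scenario"].nunique() < 2:
        raise ValueError("scope='all' requires both scenarios present")
    dropped = tuple(ln for ln in all_lines if ln not in set(df["line"]))

    lines = pd.Categorical(df["line"])
    years = pd.Categorical(df["year"])
    parts = [pd.get_dummies(lines, dtype=float)]
    ydum = pd.get_dummies(years, drop_first=True, dtype=float, prefix="year")
    parts.append(ydum)
    if scope == "all":
        sdum = pd.get_dummies(pd.Categorical(df["scenario"]), drop_first=True,
                              dtype=float, prefix="scen")
        parts.append(sdum)
        for yc in ydum.columns:
            for sc in sdum.columns:
                parts.append((ydum[yc] * sdum[sc]).rename(f"{yc}:{sc}"))
    X = pd.concat([p.reset_index(drop=True) for p in parts], axis=1)
    yvec = df[trait].to_numpy(dtype=float)
    coefs, *_ = np.linalg.lstsq(X.to_numpy(), yvec, rcond=None)
    coefs = pd.Series(coefs, index=X.columns)

    n_lines = len(lines.categories)
    line_coef = coefs.iloc[:n_lines].to_numpy()
    adj = coefs.iloc[n_lines:]
    year_cats = list(years.categories)
    if scope == "all":
        scen_cats = [s for s in SCENARIOS if s in set(df["scenario"])]
        grid_adj = []
        for yv in year_cats:
            for sv in scen_cats:
                a = 0.0
                yname = f"year_{yv}"
                sname = f"scen_{sv}"
                if yname in adj.index:
                    a += adj[yname]
                if sname in adj.index:
                    a += adj[sname]
                iname = f"{yname}:{sname}"
                if iname in adj.index:
                    a += adj[iname]
                grid_adj.append(a)
    else:
        grid_adj = [adj.get(f"year_{yv}", 0.0) for yv in year_cats]
    offset = float(np.mean(grid_adj))
    values = pd.Series(line_coef + offset,
                       index=pd.Index(lines.categories, name="line"),
                       name=f"lsmean_{scope}")
    return LsMeans(values=values, scope=scope, dropped_lines=dropped)


# ----------------------------------------------------------------------
def anova_r2_table(corrected: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Per-factor r2 percentages from a sequential (type-I) ANOVA.

    All terms of the variance-decomposition model are entered as fixed, in the
    order genetic, scenario, genetic x scenario, year, genetic x year,
    year x scenario; r2 = 100 * SS(term) / SS(total), plus a residual row.
    The column sums to 100 by construction.
    """
    validate_phenotypes(corrected, trait)
    df = corrected.loc[~corrected["is_check"]].dropna(subset=[trait]).copy()
    yv = df[trait].to_numpy(dtype=float)
    if np.allclose(yv.var(), 0.0):
        raise ValueError("zero total variance: r2 decomposition undefined")
    df = df.rename(columns={trait: "_y"})
    df["line"] = df["line"].astype(str)
    df["year"] = df["year"].astype(str)
    model = ols(
        "_y ~ C(line) + C(scenario) + C(line):C(scenario) + C(year) "
        "+ C(line):C(year) + C(year):C(scenario)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=1)
    ss = aov["sum_sq"]
    total = ss.sum()
    labels = {
        "C(line)": "genetic",
        "C(scenario)": "scenario",
        "C(line):C(scenario)": "genetic_x_scenario",
        "C(year)": "year",
        "C(line):C(year)": "genetic_x_year",
        "C(year):C(scenario)": "year_x_scenario",
        "Residual": "residual",
    }
    out = pd.DataFrame({
        "factor": [labels.get(ix, ix) for ix in ss.index],
        "r2_percent": 100.0 * ss.to_numpy() / total,
    })
    return out
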