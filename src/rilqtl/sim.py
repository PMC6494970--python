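"""Synthetic biparental RIL trial generator.

Emulates a maize F271 x Cm484 recombinant-inbred-line experiment: a
multi-chromosome genetic map, SSD-derived RIL genotypes (mosaics of the two
parental genomes), and plot-level phenotypes from a randomized augmented bloc
design run over several years under irrigated (I) and non-irrigated (NI)
scenarios, with replicated parental checks in every bloc.

Allele coding is +1 for the F271-type allele and -1 for the Cm484-type allele;
missing calls are NaN.  Planted QTLs carry an additive (constitutive) effect
and optionally a scenario-dependent (responsive) effect expressed only under
NI, so the downstream scan has a known ground truth to recover.

All randomness flows from a single master seed through named child streams
(map, genotypes, missingness, phenotypes), so every stage is reproducible in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "RILGenotypes",
    "QTLEffectSpec",
    "TrialDesign",
    "TrueComponents",
    "SimulatedTrial",
    "simulate_genetic_map",
    "simulate_ril_genotypes",
    "inject_missing",
    "simulate_trial_phenotypes",
    "haldane_r",
    "ril_switch_prob",
    "child_seed",
]

P1_ALLELE = 1.0   # F271-type
P2_ALLELE = -1.0  # Cm484-type

_STREAMS = {"map": 11, "genotypes": 23, "missing": 37, "phenotypes": 53}


def child_seed(master_seed: int, stream: str) -> np.random.SeedSequence:
    """Named, documented sub-stream of the master seed."""
    return np.random.SeedSequence(int(master_seed), spawn_key=(_STREAMS[stream],))


def haldane_r(d_cm) -> np.ndarray:
    """Haldane map function: recombination fraction for a distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def ril_switch_prob(d_cm) -> np.ndarray:
    """Expected allele-switch probability between adjacent markers in a
    selfing-derived RIL: R = 2r / (1 + 2r) with Haldane r."""
    r = haldane_r(d_cm)
    return 2.0 * r / (1.0 + 2.0 * r)


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class GeneticMap:
    """Ordered markers with cM positions on chromosomes."""

    table: pd.DataFrame  # columns: marker, chrom, pos_cM (map order)
    chromosomes: tuple   # of (chrom_id, length_cM)

    def __post_init__(self):
        t = self.table
        required = {"marker", "chrom", "pos_cM"}
        if not required.issubset(t.columns):
            raise ValueError(f"map table needs columns {sorted(required)}")
        if t["marker"].duplicated().any():
            dup = t.loc[t["marker"].duplicated(), "marker"].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r}")
        if (t["pos_cM"] < 0).any():
            raise ValueError("negative marker position")
        lengths = dict(self.chromosomes)
        for chrom, grp in t.groupby("chrom", sort=False):
            pos = grp["pos_cM"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
            if chrom not in lengths:
                raise ValueError(f"chromosome {chrom} missing from length list")
            if pos[-1] > lengths[chrom] + 1e-9:
                raise ValueError(f"marker beyond chromosome length on {chrom}")

    @property
    def markers(self) -> pd.Index:
        return pd.Index(self.table["marker"])

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def total_length_cM(self) -> float:
        return float(sum(length for _, length in self.chromosomes))

    def positions(self, chrom) -> pd.Series:
        grp = self.table[self.table["chrom"] == chrom]
        return grp.set_index("marker")["pos_cM"]


@dataclass(frozen=True)
class RILGenotypes:
    """Lines x markers matrix of parental-allele codes (+1 / -1 / NaN)."""

    calls: pd.DataFrame  # index = line ids, columns = marker ids

    def __post_init__(self):
        vals = self.calls.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == P1_ALLELE) | (vals == P2_ALLELE)
        if not ok.all():
            raise ValueError("genotype calls must be +1, -1 or NaN")
        if self.calls.index.duplicated().any():
            raise ValueError("duplicate line ids")
        if self.calls.columns.duplicated().any():
            raise ValueError("duplicate marker ids")

    @property
    def line_ids(self) -> pd.Index:
        return self.calls.index

    @property
    def marker_ids(self) -> pd.Index:
        return self.calls.columns

    def missing_fraction(self) -> pd.Series:
        return self.calls.isna().mean(axis=0)


@dataclass(frozen=True)
class QTLEffectSpec:
    """Ground-truth QTL planted at a map marker.

    additive_effect: half the difference between homozygote class means
    (constitutive part, in trait units).  interaction_effect: additional
    allele effect expressed only in the NI scenario (responsive part).
    """

    anchor_marker: str
    additive_effect: float = 0.0
    interaction_effect: float = 0.0

    def __post_init__(self):
        if not (np.isfinite(self.additive_effect)
                and np.isfinite(self.interaction_effect)):
            raise ValueError("QTL effects must be finite")


@dataclass(frozen=True)
class TrialDesign:
    """Augmented bloc design: unreplicated RILs plus parental checks per bloc.

    blocs_per_year gives the replicate (bloc) count of each year within each
    irrigation scenario; the trial defaults mirror 15 repetitions in the first
    year and 8 in the two following ones.
    """

    years: tuple = (2013, 2014, 2015)
    scenarios: tuple = ("I", "NI")
    blocs_per_year: dict = field(
        default_factory=lambda: {2013: 15, 2014: 8, 2015: 8}
    )
    check_lines: tuple = ("F271", "Cm484")
    ril_reps_per_scenario_year: int = 1

    def __post_init__(self):
        if len(self.years) < 1:
            raise ValueError("need at least one year")
        if tuple(self.scenarios) != ("I", "NI") and len(self.scenarios) != 2:
            raise ValueError("exactly two irrigation scenarios are required")
        for y in self.years:
            if self.blocs_per_year.get(y, 0) < 1:
                raise ValueError(f"year {y} needs >= 1 bloc")
        if self.ril_reps_per_scenario_year < 1:
            raise ValueError("ril_reps_per_scenario_year must be positive")

    @property
    def n_blocs_total(self) -> int:
        return len(self.scenarios) * sum(self.blocs_per_year[y] for y in self.years)


@dataclass(frozen=True)
class TrueComponents:
    """Generating model pieces: variances, intercept and fixed shifts."""

    sigma2_g: float = 4.0
    sigma2_gy: float = 1.0
    sigma2_ge: float = 1.0
    sigma2_bloc: float = 1.0
    sigma2_E: float = 4.0
    mu: float = 50.0
    year_effects: dict = field(
        default_factory=lambda: {2013: 0.0, 2014: 1.0, 2015: -1.0}
    )
    scenario_effects: dict = field(default_factory=lambda: {"I": 0.0, "NI": -5.0})
    year_x_scenario_effects: dict = field(default_factory=dict)
    check_effects: dict = field(
        default_factory=lambda: {"F271": 2.0, "Cm484": -2.0}
    )

    def __post_init__(self):
        for name in ("sigma2_g", "sigma2_gy", "sigma2_ge", "sigma2_bloc", "sigma2_E"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SimulatedTrial:
    """Phenotype table plus the generating truth, for recovery tests."""

    phenotypes: pd.DataFrame
    trait: str
    line_effects: pd.Series
    gy_effects: pd.Series       # index (line, year)
    ge_effects: pd.Series       # index (line, scenario)
    bloc_effects: pd.Series     # index (year, scenario, bloc)
    plot_components: pd.DataFrame
    qtls: tuple
    components: TrueComponents
    design: TrialDesign


# ----------------------------------------------------------------------
def simulate_genetic_map(n_chrom: int = 10, markers_per_chrom: int = 100,
                         chrom_length_cM: float = 235.5,
                         seed: int = 0) -> GeneticMap:
    """Random genetic map: first/last markers pinned at 0 and the chromosome
    end, interior positions uniform then sorted.  Defaults give a 10-chromosome,
    1,000-marker, 2,355 cM map."""
    if n_chrom < 1 or markers_per_chrom < 1:
        raise ValueError("marker and chromosome counts must be >= 1")
    if chrom_length_cM <= 0:
        raise ValueError("chromosome length must be positive")
    rng = np.random.default_rng(child_seed(seed, "map"))
    rows = []
    chroms = []
    for c in range(1, n_chrom + 1):
        chrom = f"chr{c}"
        chroms.append((chrom, float(chrom_length_cM)))
        m = markers_per_chrom
        if m == 1:
            pos = np.array([0.0])
        else:
            while True:
                interior = np.sort(rng.uniform(0.0, chrom_length_cM, size=m - 2))
                pos = np.concatenate([[0.0], interior, [chrom_length_cM]])
                if np.all(np.diff(pos) > 0):
                    break
        for i, p in enumerate(pos, start=1):
            rows.append((f"chr{c}_m{i:04d}", chrom, float(p)))
    table = pd.DataFrame(rows, columns=["marker", "chrom", "pos_cM"])
    return GeneticMap(table=table, chromosomes=tuple(chroms))


def simulate_ril_genotypes(gmap: GeneticMap, n_lines: int,
                           seed: int = 0) -> RILGenotypes:
    """SSD RIL genotypes: per chromosome, a first-order Markov mosaic with
    marker-to-marker switch probability R = 2r/(1+2r), Haldane r, no
    interference.  Lines are fully homozygous."""
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    if gmap.n_markers == 0:
        raise ValueError("empty genetic map")
    rng = np.random.default_rng(child_seed(seed, "genotypes"))
    line_ids = [f"RIL{i + 1:03d}" for i in range(n_lines)]
    cols = {}
    for chrom, _ in gmap.chromosomes:
        pos = gmap.positions(chrom)
        if pos.empty:
            continue
        m = len(pos)
        first = rng.choice([P1_ALLELE, P2_ALLELE], size=n_lines)
        geno = np.empty((n_lines, m))
        geno[:, 0] = first
        if m > 1:
            R = ril_switch_prob(np.diff(pos.to_numpy()))
            switches = rng.random((n_lines, m - 1)) < R[None, :]
            flips = np.where(switches, -1.0, 1.0)
            geno[:, 1:] = first[:, None] * np.cumprod(flips, axis=1)
        for j, marker in enumerate(pos.index):
            cols[marker] = geno[:, j]
    calls = pd.DataFrame(cols, index=pd.Index(line_ids, name="line"))
    calls = calls[gmap.markers]  # enforce map order
    return RILGenotypes(calls=calls)


def inject_missing(genotypes: RILGenotypes, rate: float,
                   seed: int = 0) -> RILGenotypes:
    """Set each call to missing independently with the given probability."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("missing rate must be in [0, 1)")
    if rate == 0.0:
        return RILGenotypes(calls=genotypes.calls.copy())
    rng = np.random.default_rng(child_seed(seed, "missing"))
    vals = genotypes.calls.to_numpy(dtype=float).copy()
    mask = rng.random(vals.shape) < rate
    vals[mask] = np.nan
    return RILGenotypes(
        calls=pd.DataFrame(vals, index=genotypes.calls.index,
                           columns=genotypes.calls.columns)
    )


# ----------------------------------------------------------------------
def _qtl_contribution(calls: pd.DataFrame, qtls, scenario_is_ni: bool):
    """Per-line summed QTL effect for one scenario; missing alleles count 0."""
    total = pd.Series(0.0, index=calls.index)
    for q in qtls:
        if q.anchor_marker not in calls.columns:
            raise ValueError(f"anchor marker {q.anchor_marker!r} not genotyped")
        x = calls[q.anchor_marker].fillna(0.0)
        eff = q.additive_effect + (q.interaction_effect if scenario_is_ni else 0.0)
        total = total + x * eff
    return total


def simulate_trial_phenotypes(genotypes: RILGenotypes, qtls=(),
                              design: TrialDesign | None = None,
                              components: TrueComponents | None = None,
                              seed: int = 0,
                              trait: str = "trait") -> SimulatedTrial:
    """Plot-level phenotypes for the augmented multi-year two-scenario trial.

    Each RIL contributes ril_reps_per_scenario_year plots per (year, scenario),
    assigned to blocs round-robin after a random shuffle; both checks appear
    once in every bloc.  Plot value = mu + year + scenario + year x scenario
    + bloc draw + polygenic line draw + G x Y draw + G x E draw + planted QTL
    effects (sign by the line's allele, NI part only under NI) + residual.
    """
    design = design or TrialDesign()
    components = components or TrueComponents()
    qtls = tuple(qtls)
    for q in qtls:
        if q.anchor_marker not in genotypes.marker_ids:
            raise ValueError(f"anchor marker {q.anchor_marker!r} absent from genotypes")
    rng = np.random.default_rng(child_seed(seed, "phenotypes"))
    c = components
    lines = list(genotypes.line_ids)

    g = pd.Series(rng.normal(0.0, np.sqrt(c.sigma2_g), len(lines)), index=lines)
    gy_index = pd.MultiIndex.from_product([lines, design.years],
                                          names=["line", "year"])
    gy = pd.Series(rng.normal(0.0, np.sqrt(c.sigma2_gy), len(gy_index)),
                   index=gy_index)
    ge_index = pd.MultiIndex.from_product([lines, design.scenarios],
                                          names=["line", "scenario"])
    ge = pd.Series(rng.normal(0.0, np.sqrt(c.sigma2_ge), len(ge_index)),
                   index=ge_index)
    bloc_index = pd.MultiIndex.from_tuples(
        [(y, s, b) for y in design.years for s in design.scenarios
         for b in range(1, design.blocs_per_year[y] + 1)],
        names=["year", "scenario", "bloc"],
    )
    bloc = pd.Series(rng.normal(0.0, np.sqrt(c.sigma2_bloc), len(bloc_index)),
                     index=bloc_index)

    qtl_by_scen = {
        s: _qtl_contribution(genotypes.calls, qtls, scenario_is_ni=(s == "NI"))
        for s in design.scenarios
    }

    records = []
    comp_rows = []
    for year in design.years:
        n_blocs = design.blocs_per_year[year]
        for scen in design.scenarios:
            fixed = (c.mu + c.year_effects.get(year, 0.0)
                     + c.scenario_effects.get(scen, 0.0)
                     + c.year_x_scenario_effects.get((year, scen), 0.0))
            # augmented layout: shuffle RIL plots, deal them across blocs
            plots = lines * design.ril_reps_per_scenario_year
            order = rng.permutation(len(plots))
            for k, idx in enumerate(order):
                line = plots[idx]
                b = k % n_blocs + 1
                records.append((line, year, scen, b, False))
                comp_rows.append((fixed, bloc[(year, scen, b)], g[line],
                                  gy[(line, year)], ge[(line, scen)],
                                  qtl_by_scen[scen][line]))
            for b in range(1, n_blocs + 1):
                for chk in design.check_lines:
                    records.append((chk, year, scen, b, True))
                    comp_rows.append(
                        (fixed + c.check_effects.get(chk, 0.0),
                         bloc[(year, scen, b)], 0.0, 0.0, 0.0, 0.0))

    pheno = pd.DataFrame(records,
                         columns=["line", "year", "scenario", "bloc", "is_check"])
    comp = pd.DataFrame(
        comp_rows, columns=["fixed", "bloc", "g", "gy", "ge", "qtl"])
    comp["residual"] = rng.normal(0.0, np.sqrt(c.sigma2_E), len(comp))
    pheno[trait] = comp.sum(axis=1).to_numpy()
    return SimulatedTrial(
        phenotypes=pheno, trait=trait, line_effects=g, gy_effects=gy,
        ge_effects=ge, bloc_effects=bloc, plot_components=comp,
        qtls=qtls, components=components, design=design,
    )
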