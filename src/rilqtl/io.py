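"""Tabular I/O, run configuration and the end-to-end pipeline.

File dialects (all TSV, UTF-8, '#' comment headers, NA for missing):

* map:        columns ``marker  chrom  pos_cM``
* genotypes:  rows = lines, columns = markers, cells in {A, B, NA}
              (A = F271-type allele, B = Cm484-type allele)
* phenotypes: columns ``line  year  scenario  bloc  is_check  <trait>...``,
              scenario in {I, NI}

Every written file carries a header comment with the tool version, a hash of
the run configuration and the seed, so outputs are traceable and two runs
with the same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _VERSION
from .models import (BlocCorrectionModel, TraitVarianceModel, anova_r2_table,
                     lsmeans, validate_phenotypes)
from .scan import (ALPHA_DEFAULT, MarkerScanModel, annotate_qtl, cluster_qtls,
                   filter_markers)
from .sim import (GeneticMap, QTLEffectSpec, RILGenotypes, TrialDesign,
                  TrueComponents, inject_missing, simulate_genetic_map,
                  simulate_ril_genotypes, simulate_trial_phenotypes)
from .traits import correlation_matrix, pca_traits, response_table

log = logging.getLogger("rilqtl")

__all__ = [
    "read_map", "write_map", "read_genotypes", "write_genotypes",
    "read_phenotypes", "write_phenotypes", "read_tables",
    "RunConfig", "load_config", "run_pipeline", "ValidationError",
]

_GENO_CODE = {"A": 1.0, "B": -1.0}
_GENO_DECODE = {1.0: "A", -1.0: "B"}


class ValidationError(ValueError):
    """Input file or configuration failed validation."""


# ----------------------------------------------------------------------
def _meta_header(meta: dict | None) -> str:
    lines = [f"# rilqtl {_VERSION}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}: {v}")
    return "\n".join(lines) + "\n"


def _write_tsv(df: pd.DataFrame, path, meta=None, index=False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=index, na_rep="NA")
    path.write_text(_meta_header(meta) + buf.getvalue())


def _read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"], **kw)


def write_map(gmap: GeneticMap, path, meta=None) -> None:
    _write_tsv(gmap.table, path, meta=meta)


def read_map(path) -> GeneticMap:
    t = _read_tsv(path)
    need = {"marker", "chrom", "pos_cM"}
    if set(t.columns) < need:
        raise ValidationError(
            f"{path}: map header must contain {sorted(need)}, got {list(t.columns)}")
    chroms = tuple(
        (chrom, float(grp["pos_cM"].max()))
        for chrom, grp in t.groupby("chrom", sort=False))
    try:
        return GeneticMap(table=t[["marker", "chrom", "pos_cM"]], chromosomes=chroms)
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_genotypes(genotypes: RILGenotypes, path, meta=None) -> None:
    coded = genotypes.calls.replace(_GENO_DECODE)
    coded.index.name = "line"
    _write_tsv(coded, path, meta=meta, index=True)


def read_genotypes(path, gmap: GeneticMap | None = None) -> RILGenotypes:
    t = _read_tsv(path, index_col=0, dtype=str)
    bad = sorted(set(np.unique(t.fillna("NA").to_numpy())) - {"A", "B", "NA"})
    if bad:
        raise ValidationError(f"{path}: unknown genotype codes {bad}")
    calls = t.apply(lambda col: col.map(_GENO_CODE)).astype(float)
    if gmap is not None:
        unknown = [m for m in calls.columns if m not in set(gmap.markers)]
        if unknown:
            raise ValidationError(
                f"{path}: markers absent from map: {unknown[:10]}")
    try:
        return RILGenotypes(calls=calls)
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_phenotypes(pheno: pd.DataFrame, path, meta=None) -> None:
    _write_tsv(pheno, path, meta=meta)


def read_phenotypes(path) -> pd.DataFrame:
    t = _read_tsv(path)
    if "scenario" in t.columns:
        raw = t["scenario"].astype(str)
        norm = raw.str.strip().str.upper()
        if (norm != raw).any():
            log.warning("%s: normalized %d scenario codes (whitespace/case)",
                        path, int((norm != raw).sum()))
        t["scenario"] = norm
    if "is_check" in t.columns:
        t["is_check"] = t["is_check"].astype(bool)
    try:
        validate_phenotypes(t)
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
    dup_blocs = t[["year", "scenario", "bloc"]].drop_duplicates()
    if dup_blocs.duplicated(["year", "scenario", "bloc"]).any():
        raise ValidationError(f"{path}: duplicate bloc identifiers")
    return t


def read_tables(map_path, genotype_path, phenotype_path):
    """Load and cross-validate the three input tables."""
    gmap = read_map(map_path)
    geno = read_genotypes(genotype_path, gmap=gmap)
    pheno = read_phenotypes(phenotype_path)
    return gmap, geno, pheno


# ----------------------------------------------------------------------
@dataclass
class RunConfig:
    """Configuration for a pipeline run (simulation and/or analysis)."""

    outdir: str = "rilqtl_out"
    seed: int = 1
    alpha: float = ALPHA_DEFAULT
    max_missing: float = 0.15
    traits: tuple = ("trait",)
    # paths for analysis of existing data (None -> simulate)
    map_path: str | None = None
    genotype_path: str | None = None
    phenotype_path: str | None = None
    # simulation block
    n_lines: int = 261
    n_chrom: int = 10
    markers_per_chrom: int = 100
    chrom_length_cM: float = 235.5
    missing_rate: float = 0.05
    design: dict = field(default_factory=dict)
    components: dict = field(default_factory=dict)
    qtls: tuple = ()   # of dicts: anchor_marker/additive_effect/interaction_effect

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must lie strictly inside (0, 1)")
        if not (0.0 <= self.max_missing < 1.0):
            raise ValidationError("max_missing must lie in [0, 1)")
        if self.n_lines < 1:
            raise ValidationError("n_lines must be positive")

    def digest(self) -> str:
        payload = asdict(self)
        payload.pop("outdir", None)  # output location must not affect content
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def load_config(path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    data = (json.loads(text) if path.suffix == ".json" else yaml.safe_load(text))
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("traits", "qtls"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return RunConfig(**data)


def _design_from_config(cfg: RunConfig) -> TrialDesign:
    d = dict(cfg.design)
    if "blocs_per_year" in d:
        d["blocs_per_year"] = {int(k): int(v)
                               for k, v in d["blocs_per_year"].items()}
    if "years" in d:
        d["years"] = tuple(d["years"])
    if "scenarios" in d:
        d["scenarios"] = tuple(d["scenarios"])
    if "check_lines" in d:
        d["check_lines"] = tuple(d["check_lines"])
    return TrialDesign(**d)


def _components_from_config(cfg: RunConfig) -> TrueComponents:
    return TrueComponents(**cfg.components)


# ----------------------------------------------------------------------
def simulate_dataset(cfg: RunConfig):
    """Simulate map, genotypes and phenotypes per the config; returns the
    tables plus the truth bundle."""
    gmap = simulate_genetic_map(cfg.n_chrom, cfg.markers_per_chrom,
                                cfg.chrom_length_cM, seed=cfg.seed)
    geno = simulate_ril_genotypes(gmap, cfg.n_lines, seed=cfg.seed)
    if cfg.missing_rate > 0:
        geno = inject_missing(geno, cfg.missing_rate, seed=cfg.seed)
    design = _design_from_config(cfg)
    comps = _components_from_config(cfg)
    qtls = tuple(QTLEffectSpec(**q) for q in cfg.qtls)
    trials = {}
    for i, trait in enumerate(cfg.traits):
        trials[trait] = simulate_trial_phenotypes(
            geno, qtls=qtls, design=design, components=comps,
            seed=cfg.seed + 1000003 * i, trait=trait)
    pheno = trials[cfg.traits[0]].phenotypes[
        ["line", "year", "scenario", "bloc", "is_check"]].copy()
    for trait in cfg.traits:
        pheno[trait] = trials[trait].phenotypes[trait].to_numpy()
    return gmap, geno, pheno, trials


def _truth_table(trials, qtls) -> pd.DataFrame:
    rows = []
    for q in qtls:
        rows.append(("qtl", q.anchor_marker,
                     f"additive={q.additive_effect};"
                     f"interaction={q.interaction_effect}"))
    any_trial = next(iter(trials.values()))
    c = any_trial.components
    for name in ("sigma2_g", "sigma2_gy", "sigma2_ge", "sigma2_bloc",
                 "sigma2_E", "mu"):
        rows.append(("component", name, getattr(c, name)))
    return pd.DataFrame(rows, columns=["kind", "name", "value"])


def run_pipeline(cfg: RunConfig) -> dict:
    """Full pipeline: (simulate|load) -> correct -> components/h2 -> ls-means,
    responses, correlations, PCA -> scan both kinds -> declare -> r2/effects
    -> cluster -> write every table.  Deterministic given config + seed."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_sha256": cfg.digest(), "seed": cfg.seed}
    stage = "load"
    try:
        if cfg.map_path:
            gmap, geno, pheno = read_tables(cfg.map_path, cfg.genotype_path,
                                            cfg.phenotype_path)
            trials = None
        else:
            stage = "simulate"
            gmap, geno, pheno, trials = simulate_dataset(cfg)
            write_map(gmap, out / "map.tsv", meta)
            write_genotypes(geno, out / "genotypes.tsv", meta)
            write_phenotypes(pheno, out / "phenotypes.tsv", meta)
            _write_tsv(_truth_table(trials, trials[cfg.traits[0]].qtls),
                       out / "truth.tsv", meta)
        stage = "filter"
        geno_f = filter_markers(geno, max_missing=cfg.max_missing)
        log.info("filter: kept %d of %d markers",
                 len(geno_f.marker_ids), len(geno.marker_ids))

        results = {"qtls": [], "clusters": {}, "h2": {}, "components": {}}
        corrected_all = None
        comp_rows, resp_frames, scan_frames, qtl_rows = [], [], [], []
        lsm_store = {}
        for trait in cfg.traits:
            stage = f"correct[{trait}]"
            corr = BlocCorrectionModel(pheno, trait).fit()
            corrected = corr.corrected()
            corrected_all = (corrected if corrected_all is None
                             else corrected_all.assign(
                                 **{trait: corrected[trait]}))
            stage = f"stats[{trait}]"
            vres = TraitVarianceModel(corrected, trait).fit()
            vc = vres.components
            h2 = vres.heritability()
            results["components"][trait] = vc
            results["h2"][trait] = h2
            for name, val in (("sigma2_g", vc.sigma2_g), ("sigma2_gy", vc.sigma2_gy),
                              ("sigma2_ge", vc.sigma2_ge), ("sigma2_E", vc.sigma2_E),
                              ("h2", h2)):
                comp_rows.append((trait, name, val))
            lsm = {scope: lsmeans(corrected, trait, scope)
                   for scope in ("all", "I", "NI")}
            lsm_store[trait] = lsm
            resp_frames.append(response_table(
                lsm["I"].values, lsm["NI"].values).assign(trait=trait))

            stage = f"scan[{trait}]"
            scan = MarkerScanModel(corrected, geno_f, gmap, trait).fit()
            scan_frames.append(scan.table.assign(trait=trait))
            stage = f"declare[{trait}]"
            for kind in ("constitutive", "responsive"):
                for q in scan.declare(alpha=cfg.alpha, kind=kind):
                    q = annotate_qtl(q, lsm, geno_f)
                    results["qtls"].append(q)
                    qtl_rows.append((q.trait, q.kind, q.chrom, q.peak_marker,
                                     q.peak_pos_cM, q.ci_start_cM, q.ci_end_cM,
                                     q.p_peak, q.r2_percent, q.normalized_effect,
                                     q.favorable_parent))

        stage = "cluster"
        for kind in ("constitutive", "responsive"):
            clusters, singletons = cluster_qtls(results["qtls"], kind)
            results["clusters"][kind] = clusters
        stage = "report"
        _write_tsv(pd.DataFrame(comp_rows,
                                columns=["trait", "component", "estimate"]),
                   out / "components.tsv", meta)
        (out / "components.json").write_text(json.dumps(
            {t: {"sigma2_g": c.sigma2_g, "sigma2_gy": c.sigma2_gy,
                 "sigma2_ge": c.sigma2_ge, "sigma2_E": c.sigma2_E,
                 "h2": results["h2"][t]} for t, c in results["components"].items()},
            indent=2, sort_keys=True))
        _write_tsv(pd.concat(resp_frames, ignore_index=True),
                   out / "responses.tsv", meta)
        _write_tsv(pd.concat(scan_frames, ignore_index=True),
                   out / "scan.tsv", meta)
        _write_tsv(pd.DataFrame(qtl_rows, columns=[
            "trait", "kind", "chrom", "peak_marker", "peak_pos_cM",
            "ci_start_cM", "ci_end_cM", "p_peak", "r2_percent",
            "normalized_effect", "favorable_parent"]),
            out / "qtls.tsv", meta)
        cluster_payload = {
            kind: [{"cluster_id": c.cluster_id, "chrom": c.chrom,
                    "span_start_cM": c.span_start_cM,
                    "span_end_cM": c.span_end_cM,
                    "traits": list(c.traits),
                    "n_members": len(c.members)}
                   for c in results["clusters"][kind]]
            for kind in results["clusters"]}
        (out / "clusters.json").write_text(
            json.dumps(cluster_payload, indent=2, sort_keys=True))
        if len(cfg.traits) >= 2:
            joint = pd.DataFrame({t: lsm_store[t]["all"].values
                                  for t in cfg.traits}).dropna()
            _write_tsv(correlation_matrix(joint), out / "correlations.tsv",
                       meta, index=True)
            pca = pca_traits(joint)
            _write_tsv(pca.loadings, out / "pca_loadings.tsv", meta, index=True)
            _write_tsv(pca.percent_variance.to_frame(),
                       out / "pca_variance.tsv", meta, index=True)
        if corrected_all is not None:
            write_phenotypes(corrected_all, out / "corrected.tsv", meta)
        (out / "provenance.json").write_text(json.dumps(
            {"version": _VERSION, "config": asdict(cfg),
             "config_sha256": cfg.digest(), "seed": cfg.seed},
            indent=2, sort_keys=True, default=str))
        _write_summary(out, cfg, results)
    except Exception as exc:
        (out / "INCOMPLETE").write_text(f"failed at stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc
    results["outdir"] = str(out)
    results["truth"] = trials
    return results


def _write_summary(out: Path, cfg: RunConfig, results: dict) -> None:
    lines = [f"rilqtl {_VERSION} run summary",
             f"seed {cfg.seed}, alpha {cfg.alpha:g}", ""]
    for trait in cfg.traits:
        vc = results["components"][trait]
        lines.append(
            f"{trait}: h2 = {results['h2'][trait]:.3f} "
            f"(sigma2_g {vc.sigma2_g:.3g}, gy {vc.sigma2_gy:.3g}, "
            f"ge {vc.sigma2_ge:.3g}, E {vc.sigma2_E:.3g})")
    by_kind = {"constitutive": 0, "responsive": 0}
    for q in results["qtls"]:
        by_kind[q.kind] += 1
    lines.append("")
    lines.append(f"QTLs declared: {by_kind['constitutive']} constitutive, "
                 f"{by_kind['responsive']} responsive")
    for kind, clusters in results["clusters"].items():
        lines.append(f"clusters ({kind}): {len(clusters)}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
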