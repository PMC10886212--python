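"""Pipeline orchestration: QC -> structure -> LD -> scan -> annotate -> enrich.

A single :class:`PipelineConfig` (constructible from YAML) drives the whole
analysis; every stage writes its tabular outputs into a run directory and a
``manifest.json`` records the configuration and a SHA-256 checksum of each
artifact, so a rerun with identical inputs is verifiably bit-identical.
Small phenotype utilities (average daily weight gain over the 20->50 kg
growth interval, and a pooled two-sample t comparison) live here too.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import annotate as ann
from . import genotype_io as gio
from . import ld as ldmod
from . import popstruct, selscan

log = logging.getLogger("selsig")


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2 in the CLI)."""


class StageError(RuntimeError):
    """A pipeline stage failed (exit code 3 in the CLI)."""


@dataclass
class PipelineConfig:
    """Everything one run needs; ``pop1`` is the θπ-ratio numerator population."""

    genotypes: str  # VCF path, or .ped path when `plink_map` is set
    popmap: str
    out_dir: str
    pop1: str
    pop2: str
    plink_map: str | None = None
    gene_models: str | None = None
    gene_sets: str | None = None
    # QC
    callrate_min: float = 0.90
    maf_min: float = 0.05
    hwe_p_min: float = 1.0e-6
    autosomes: tuple[str, ...] = tuple(sorted(gio.PIG_AUTOSOMES, key=int))
    # structure
    n_components: int = 10
    pca_scaling: str = "patterson"
    # LD
    ld_max_dist: int = 500_000
    ld_bin_width: int = 1_000
    equalize_n: bool = True
    # scan
    window: int = 5_000_000
    step: int = 100_000
    top_frac: float = 0.01
    min_snps: int = 2
    fst_estimator: str = "nei"
    combine: str = "intersect"
    # annotation
    flank: int = 1_000
    max_flank_search: int = 1_000_000
    include_intergenic_neighbors: bool = True
    enrich_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop1 == self.pop2:
            raise ConfigError("pop1 and pop2 must differ")
        for name in ("callrate_min", "maf_min", "top_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if not 0 < self.hwe_p_min < 1:
            raise ConfigError("hwe_p_min must lie in (0, 1)")
        if self.window < self.step:
            raise ConfigError("window must be >= step")
        if self.fst_estimator not in ("nei", "wc"):
            raise ConfigError(f"unknown fst_estimator {self.fst_estimator!r}")
        if self.combine not in ("intersect", "union"):
            raise ConfigError(f"unknown combine mode {self.combine!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: YAML config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        if "autosomes" in data:
            data["autosomes"] = tuple(str(a) for a in data["autosomes"])
        return cls(**data)

    #: per-stage seed offsets fanned out from the global seed
    def stage_seed(self, stage: str) -> int:
        offsets = {"ld": 1, "scan": 2, "phenotype": 3}
        return (self.seed + offsets.get(stage, 0)) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage; returns the run directory containing all artifacts.

    Artifacts: ``qc_report.tsv``, ``filtered.vcf``, ``pca_coordinates.tsv``,
    ``pca_variance.tsv``, ``ibs_distance.tsv``, ``tree.nwk``,
    ``ld_decay.tsv``, ``windows.tsv``, ``thresholds.json``, per-direction
    ``regions_<pop>.bed`` and ``candidate_snps.tsv``, optional
    ``annotation.tsv``/``category_counts.tsv``/``enrichment_<pop>.tsv``,
    plus ``manifest.json`` with config and artifact checksums.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- load + validate ----------------------------------------------
    popmap = gio.read_popmap(cfg.popmap)
    pops = set(popmap.values())
    for p in (cfg.pop1, cfg.pop2):
        if p not in pops:
            raise ConfigError(f"population {p!r} absent from popmap")

    def stage(name: str, fn):
        log.info("stage %s: start", name)
        try:
            return fn()
        except (ConfigError,):
            raise
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    def load():
        if cfg.plink_map:
            return gio.read_plink_text(cfg.genotypes, cfg.plink_map, popmap)
        return gio.read_vcf(cfg.genotypes, popmap)

    g_raw = stage("load", load)

    # ---- QC ------------------------------------------------------------
    def qc():
        g, report = gio.qc_filter(
            g_raw,
            callrate_min=cfg.callrate_min,
            maf_min=cfg.maf_min,
            hwe_p_min=cfg.hwe_p_min,
            autosomes=cfg.autosomes,
        )
        report.write_tsv(out / "qc_report.tsv")
        gio.write_vcf(g, out / "filtered.vcf")
        return g

    g = stage("qc", qc)

    # ---- structure ------------------------------------------------------
    def structure():
        res = popstruct.pca(g, n_components=cfg.n_components, scaling=cfg.pca_scaling)
        res.to_frame().to_csv(out / "pca_coordinates.tsv", sep="\t", index=False,
                              float_format="%.10g")
        pd.DataFrame(
            {
                "component": [f"PC{k + 1}" for k in range(len(res.variance_explained))],
                "variance_explained": res.variance_explained,
            }
        ).to_csv(out / "pca_variance.tsv", sep="\t", index=False, float_format="%.10g")
        dm = popstruct.ibs_distance(g)
        dm.to_frame().to_csv(out / "ibs_distance.tsv", sep="\t", float_format="%.10g")
        popstruct.write_newick(popstruct.nj_tree(dm), out / "tree.nwk")
        return res

    pca_res = stage("structure", structure)

    # ---- LD -------------------------------------------------------------
    def ld():
        curves = ldmod.population_decay_curves(
            g,
            max_dist=cfg.ld_max_dist,
            bin_width=cfg.ld_bin_width,
            equalize_n=cfg.equalize_n,
            seed=cfg.stage_seed("ld"),
        )
        pd.concat([c.to_frame() for c in curves.values()], ignore_index=True).to_csv(
            out / "ld_decay.tsv", sep="\t", index=False, float_format="%.10g"
        )
        return curves

    ld_curves = stage("ld", ld)

    # ---- scan -----------------------------------------------------------
    def scan():
        windows = selscan.scan_windows(
            g, cfg.pop1, cfg.pop2,
            window=cfg.window, step=cfg.step, fst_estimator=cfg.fst_estimator,
        )
        for col in ("fst", "pi_ratio"):
            try:
                windows[f"{col}_scaled"] = selscan.minmax_scale(windows[col].to_numpy())
            except ValueError:
                windows[f"{col}_scaled"] = np.nan
        windows.to_csv(out / "windows.tsv", sep="\t", index=False, float_format="%.10g")
        calls = selscan.call_sweeps(
            windows[selscan.WINDOW_COLUMNS], g,
            top_frac=cfg.top_frac, min_snps=cfg.min_snps, combine=cfg.combine,
            pop1=cfg.pop1, pop2=cfg.pop2,
        )
        calls.write_thresholds(out / "thresholds.json")
        selscan.write_regions_bed(calls.regions_pop1, out / f"regions_{cfg.pop1}.bed",
                                  name=cfg.pop1)
        selscan.write_regions_bed(calls.regions_pop2, out / f"regions_{cfg.pop2}.bed",
                                  name=cfg.pop2)
        calls.candidate_snps.to_csv(out / "candidate_snps.tsv", sep="\t", index=False)
        return calls

    calls = stage("scan", scan)

    # ---- annotate + enrich ---------------------------------------------
    if cfg.gene_models:
        def annotate_stage():
            genes = ann.load_gene_models(cfg.gene_models)
            snps = ann.annotate_snps(
                calls.candidate_snps, genes,
                flank=cfg.flank, max_flank_search=cfg.max_flank_search,
            )
            frame = ann.annotation_frame(snps)
            frame["direction"] = calls.candidate_snps["direction"].to_numpy()
            frame.to_csv(out / "annotation.tsv", sep="\t", index=False)
            ann.category_counts(snps).to_csv(
                out / "category_counts.tsv", sep="\t", index=False
            )
            if cfg.gene_sets:
                gmt = ann.read_gmt(cfg.gene_sets)
                universe = [gm.gene_id for gm in genes]
                for pop in (cfg.pop1, cfg.pop2):
                    mask = frame["direction"] == pop
                    cand = ann.candidate_genes(
                        [s for s, m in zip(snps, mask) if m],
                        include_intergenic_neighbors=cfg.include_intergenic_neighbors,
                    )
                    if cand:
                        res = ann.hypergeom_enrich(cand, universe, gmt,
                                                   alpha=cfg.enrich_alpha)
                        ann.enrichment_frame(res).to_csv(
                            out / f"enrichment_{pop}.tsv", sep="\t", index=False
                        )
            return snps

        stage("annotate", annotate_stage)

    # ---- manifest -------------------------------------------------------
    artifacts = sorted(
        p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(cfg).items()},
        "inputs": {
            "genotypes": _sha256(Path(cfg.genotypes)),
            "popmap": _sha256(Path(cfg.popmap)),
        },
        "artifacts": {name: _sha256(out / name) for name in artifacts},
        "summary": {
            "n_snps_retained": int(g.n_variants),
            "pc1_variance_explained": float(pca_res.variance_explained[0]),
            "r2_threshold_distance": {
                p: ldmod.r2_threshold_distance(c) for p, c in ld_curves.items()
            },
            "n_candidate_snps": {
                cfg.pop1: int((calls.candidate_snps["direction"] == cfg.pop1).sum()),
                cfg.pop2: int((calls.candidate_snps["direction"] == cfg.pop2).sum()),
            },
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("pipeline complete: %s", out)
    return out


# ---------------------------------------------------------------------------
# phenotype utilities
# ---------------------------------------------------------------------------

def adwg(age_at_20kg: float, age_at_50kg: float) -> float:
    """Average daily weight gain (kg/day) over the 20->50 kg growth interval."""
    interval = age_at_50kg - age_at_20kg
    if interval <= 0:
        raise ValueError("age_at_50kg must exceed age_at_20kg")
    return (50.0 - 20.0) / interval


def compare_phenotypes(
    group1: "np.ndarray | list[float]",
    group2: "np.ndarray | list[float]",
    welch: bool = False,
) -> dict[str, float]:
    """Two-sample t comparison (pooled-variance Student's t by default).

    Returns t, df, two-tailed p and the per-group medians. Degenerate case:
    zero variance in both groups with equal means yields t=0, p=1; with
    unequal means the test statistic is undefined and an error is raised.
    """
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return {
                "t": 0.0, "df": float(len(a) + len(b) - 2), "p": 1.0,
                "median1": float(np.median(a)), "median2": float(np.median(b)),
            }
        raise ValueError("zero variance with unequal means: t undefined")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return {
        "t": float(res.statistic),
        "df": float(res.df),
        "p": float(res.pvalue),
        "median1": float(np.median(a)),
        "median2": float(np.median(b)),
    }
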