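"""Genotype input/output and marker quality control.

The analysis substrate is a :class:`GenotypeMatrix`: a samples x variants
matrix of alternate-allele dosages (0/1/2, ``MISSING`` = -1) together with a
variant table and a sample table carrying population labels. Genotypes are
read from VCF (via :mod:`cyvcf2`) or PLINK-style ``.ped``/``.map`` text, and
QC applies the standard chip filters — per-variant call rate, autosome
membership, minor-allele frequency and a Hardy–Weinberg exact test — in a
fixed, audited order.

Coordinates are 1-based inclusive internally and in TSV outputs; BED written
elsewhere in the package is 0-based half-open.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("selsig")

#: Sentinel dosage for a missing diploid call.
MISSING: int = -1

#: Autosome names of the pig genome; the QC default keeps only these.
PIG_AUTOSOMES: frozenset[str] = frozenset(str(c) for c in range(1, 19))

VARIANT_COLUMNS = ["chrom", "pos", "vid", "ref", "alt"]
SAMPLE_COLUMNS = ["sample_id", "population"]


class GenotypeIOError(ValueError):
    """Raised for malformed genotype files or inconsistent sample maps."""


@dataclass(frozen=True)
class GenotypeMatrix:
    """Dosage matrix plus variant and sample metadata.

    Attributes
    ----------
    calls
        ``int8`` array of shape (n_samples, n_variants); entries in
        {0, 1, 2, MISSING}.
    variants
        DataFrame with columns ``chrom, pos, vid, ref, alt`` (pos 1-based).
    samples
        DataFrame with columns ``sample_id, population``.
    """

    calls: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or MISSING")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.variants.duplicated(subset=["chrom", "pos"]).any():
            raise ValueError("duplicate (chrom, pos) variant coordinates")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_variants(self) -> int:
        return self.calls.shape[1]

    @property
    def populations(self) -> list[str]:
        """Distinct population labels in first-seen order."""
        return list(dict.fromkeys(self.samples["population"]))

    def sample_indices(self, population: str) -> np.ndarray:
        idx = np.flatnonzero((self.samples["population"] == population).to_numpy())
        if idx.size == 0:
            raise KeyError(f"unknown population label: {population!r}")
        return idx

    def subset_variants(self, mask_or_index: np.ndarray) -> "GenotypeMatrix":
        """New matrix keeping variants selected by boolean mask or index array."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            calls=self.calls[:, idx],
            variants=self.variants.iloc[idx].reset_index(drop=True),
            samples=self.samples,
        )

    def subset_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            calls=self.calls[index, :],
            variants=self.variants,
            samples=self.samples.iloc[index].reset_index(drop=True),
        )

    def alt_freq(self, sample_index: np.ndarray | None = None) -> np.ndarray:
        """Alternate-allele frequency per variant over called genotypes.

        Variants with no called genotype in the chosen samples get ``nan``.
        """
        calls = self.calls if sample_index is None else self.calls[sample_index, :]
        called = calls != MISSING
        n_alleles = 2 * called.sum(axis=0)
        alt = np.where(called, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)


@dataclass(frozen=True)
class QCThresholds:
    callrate_min: float = 0.90
    maf_min: float = 0.05
    hwe_p_min: float = 1.0e-6
    autosomes: frozenset[str] = PIG_AUTOSOMES


@dataclass(frozen=True)
class QCReport:
    """Per-stage removal counts for a QC pass; stages apply in listed order."""

    n_input: int
    n_removed_callrate: int
    n_removed_nonautosomal: int
    n_removed_maf: int
    n_removed_hwe: int
    n_retained: int
    thresholds: QCThresholds

    def __post_init__(self) -> None:
        removed = (
            self.n_removed_callrate
            + self.n_removed_nonautosomal
            + self.n_removed_maf
            + self.n_removed_hwe
        )
        if self.n_input - removed != self.n_retained:
            raise ValueError("QC bookkeeping does not balance")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("input", self.n_input),
            ("removed_callrate", self.n_removed_callrate),
            ("removed_nonautosomal", self.n_removed_nonautosomal),
            ("removed_maf", self.n_removed_maf),
            ("removed_hwe", self.n_removed_hwe),
            ("retained", self.n_retained),
        ]
        return pd.DataFrame(rows, columns=["stage", "n"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# population map
# ---------------------------------------------------------------------------

def read_popmap(path: str | Path) -> dict[str, str]:
    """Read a two-column sample_id<TAB>population map."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise GenotypeIOError(f"popmap {path}: expected 2 tab-separated columns")
    if df[0].duplicated().any():
        dup = df[0][df[0].duplicated()].iloc[0]
        raise GenotypeIOError(f"popmap {path}: duplicate sample id {dup!r}")
    return dict(zip(df[0], df[1]))


def write_popmap(samples: pd.DataFrame, path: str | Path) -> None:
    samples[SAMPLE_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def _sample_table(sample_ids: Sequence[str], popmap: Mapping[str, str]) -> pd.DataFrame:
    missing = [s for s in sample_ids if s not in popmap]
    if missing:
        raise GenotypeIOError(
            f"samples absent from population map: {', '.join(missing[:5])}"
            + ("..." if len(missing) > 5 else "")
        )
    return pd.DataFrame(
        {"sample_id": list(sample_ids), "population": [popmap[s] for s in sample_ids]}
    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    popmap: str | Path | Mapping[str, str],
    *,
    keep_first_alt: bool = False,
) -> GenotypeMatrix:
    """Read diploid GT calls from a VCF into a GenotypeMatrix.

    Dosage is the ALT-allele count; ``./.`` and half-calls become MISSING.
    Multi-allelic records are rejected by default (counted in the log);
    with ``keep_first_alt`` the first ALT is kept and any genotype carrying
    a higher allele index is set MISSING.
    """
    from cyvcf2 import VCF

    pm = popmap if isinstance(popmap, Mapping) else read_popmap(popmap)
    vcf = VCF(str(path))
    samples = _sample_table(vcf.samples, pm)

    rows, columns, n_multi = [], [], 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            if not keep_first_alt or len(rec.ALT) == 0:
                n_multi += 1
                continue
        # genotypes: [allele0, allele1, phased]; -1 encodes a missing allele
        g = np.array([gt[:2] for gt in rec.genotypes], dtype=np.int16)
        dose = g.sum(axis=1).astype(np.int8)
        dose[(g < 0).any(axis=1)] = MISSING
        if len(rec.ALT) > 1:  # keep_first_alt: drop calls using ALT2+
            dose[(g > 1).any(axis=1)] = MISSING
            n_multi += 1
        columns.append(dose)
        rows.append(
            (
                rec.CHROM,
                rec.POS,
                rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}",
                rec.REF,
                rec.ALT[0] if rec.ALT else ".",
            )
        )
    if n_multi:
        log.info("read_vcf: %d multi-allelic records %s", n_multi,
                 "truncated to first ALT" if keep_first_alt else "rejected")
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(calls=calls, variants=variants, samples=samples)


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as a minimal GT-only VCF (deterministic byte output)."""
    gtmap = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    chroms = list(dict.fromkeys(g.variants["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=selsig\n")
        for chrom in chroms:
            end = int(g.variants.loc[g.variants["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={end + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples["sample_id"])
            + "\n"
        )
        variants = g.variants.itertuples(index=False)
        for j, v in enumerate(variants):
            gts = "\t".join(gtmap[int(d)] for d in g.calls[:, j])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.vid}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# PLINK text (.ped / .map)
# ---------------------------------------------------------------------------

def read_plink_text(
    ped: str | Path,
    map_: str | Path,
    popmap: str | Path | Mapping[str, str],
) -> GenotypeMatrix:
    """Read PLINK whitespace-separated .ped/.map text files.

    The ALT (counted) allele per marker is the minor allele over all samples,
    ties broken lexicographically; ``0 0`` is a missing call.
    """
    pm = popmap if isinstance(popmap, Mapping) else read_popmap(popmap)

    mp = pd.read_csv(map_, sep=r"\s+", header=None, dtype=str)
    if mp.shape[1] != 4:
        raise GenotypeIOError(f"{map_}: .map must have 4 columns, got {mp.shape[1]}")
    n_var = len(mp)

    sample_ids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped) as fh:
        for i, line in enumerate(fh):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_var:
                raise GenotypeIOError(
                    f"{ped}: record {i} has {len(fields)} fields, "
                    f"expected {6 + 2 * n_var} for {n_var} markers"
                )
            sample_ids.append(fields[1])
            allele_rows.append(fields[6:])

    samples = _sample_table(sample_ids, pm)
    a1 = np.array([r[0::2] for r in allele_rows], dtype=object)
    a2 = np.array([r[1::2] for r in allele_rows], dtype=object)

    calls = np.empty((len(sample_ids), n_var), dtype=np.int8)
    refs, alts = [], []
    for j in range(n_var):
        col = np.concatenate([a1[:, j], a2[:, j]])
        obs = sorted(set(col) - {"0"})
        if len(obs) > 2:
            raise GenotypeIOError(f"{ped}: marker {mp.iloc[j, 1]} has >2 alleles")
        if not obs:
            refs.append("N")
            alts.append("N")
            calls[:, j] = MISSING
            continue
        miss = (a1[:, j] == "0") | (a2[:, j] == "0")
        if len(obs) == 1:
            # monomorphic: the single observed allele is REF, ALT unseen
            refs.append(obs[0])
            alts.append("N")
            dose = np.zeros(len(sample_ids), dtype=np.int8)
        else:
            counts = {a: int((col == a).sum()) for a in obs}
            # minor allele = ALT; lexicographic tie-break
            alt = min(obs, key=lambda a: (counts[a], a))
            ref = obs[0] if obs[1] == alt else obs[1]
            refs.append(ref)
            alts.append(alt)
            dose = (a1[:, j] == alt).astype(np.int8) + (a2[:, j] == alt).astype(np.int8)
        dose[miss] = MISSING
        calls[:, j] = dose

    variants = pd.DataFrame(
        {
            "chrom": mp[0],
            "pos": mp[3].astype(np.int64),
            "vid": mp[1],
            "ref": refs,
            "alt": alts,
        }
    )
    # monomorphic PLINK markers give ref == alt; disambiguate to keep invariant
    same = variants["ref"] == variants["alt"]
    variants.loc[same, "ref"] = variants.loc[same, "ref"] + "*"
    return GenotypeMatrix(calls=calls, variants=variants, samples=samples)


def write_plink_text(g: GenotypeMatrix, ped: str | Path, map_: str | Path) -> None:
    """Write .ped/.map; ALT is written as allele ``alt``, REF as ``ref``."""
    with open(map_, "w") as fh:
        for v in g.variants.itertuples(index=False):
            fh.write(f"{v.chrom}\t{v.vid}\t0\t{v.pos}\n")
    with open(ped, "w") as fh:
        for i, s in enumerate(g.samples.itertuples(index=False)):
            parts = [s.population, s.sample_id, "0", "0", "0", "-9"]
            for j in range(g.n_variants):
                d = int(g.calls[i, j])
                ref = g.variants.at[j, "ref"]
                alt = g.variants.at[j, "alt"]
                pair = {
                    0: (ref, ref),
                    1: (ref, alt),
                    2: (alt, alt),
                    MISSING: ("0", "0"),
                }[d]
                parts.extend(pair)
            fh.write(" ".join(parts) + "\n")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy–Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count whose conditional probability is <= that of the
    observed count (the standard exact formulation for biallelic genotype
    counts). Returns a p-value in (0, 1].
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = n_Aa + 2 * n_aa  # minor-allele-agnostic: formula is symmetric
    n_A = 2 * n - n_a
    rare = min(n_A, n_a)

    # log P(n_het | allele counts) up to a shared constant:
    #   P ∝ n! / (nAA! nAa! naa!) * 2^nAa
    lg = math.lgamma

    def logp(het: int) -> float:
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        return het * math.log(2.0) - lg(hom_rare + 1) - lg(het + 1) - lg(hom_common + 1)

    hets = range(rare % 2, rare + 1, 2)
    lps = np.array([logp(h) for h in hets])
    probs = np.exp(lps - lps.max())
    probs /= probs.sum()
    obs = probs[list(hets).index(n_Aa)]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def hwe_pvalues(
    g: GenotypeMatrix, sample_index: np.ndarray | None = None
) -> np.ndarray:
    """Exact HWE p per variant over the chosen samples (1.0 if uncalled)."""
    calls = g.calls if sample_index is None else g.calls[sample_index, :]
    out = np.ones(g.n_variants)
    for j in range(g.n_variants):
        col = calls[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            continue
        out[j] = hwe_exact_test(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )
    return out


def qc_filter(
    g: GenotypeMatrix,
    callrate_min: float = 0.90,
    maf_min: float = 0.05,
    hwe_p_min: float = 1.0e-6,
    autosomes: Iterable[str] = PIG_AUTOSOMES,
    hwe_per_population: bool = False,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply chip QC in the fixed order: call rate, autosome, MAF, HWE.

    MAF and (by default) HWE are computed on all samples pooled. Pooling two
    diverged populations inflates HWE failures (Wahlund effect);
    ``hwe_per_population`` instead tests within each population and removes a
    variant only if it fails in some population.
    """
    if g.n_variants == 0:
        raise ValueError("empty genotype matrix")
    autosomes = frozenset(str(a) for a in autosomes)
    keep = np.ones(g.n_variants, dtype=bool)

    called_frac = (g.calls != MISSING).mean(axis=0)
    fail_cr = called_frac < callrate_min
    n_cr = int(fail_cr.sum())
    keep &= ~fail_cr

    fail_auto = ~g.variants["chrom"].astype(str).isin(autosomes).to_numpy()
    n_auto = int((fail_auto & keep).sum())
    keep &= ~fail_auto

    p = g.alt_freq()
    maf = np.fmin(p, 1.0 - p)
    fail_maf = ~(maf >= maf_min)  # nan freq (all-missing) also fails
    n_maf = int((fail_maf & keep).sum())
    keep &= ~fail_maf

    sub = g.subset_variants(keep)
    if hwe_per_population:
        pvals = np.ones(sub.n_variants)
        for pop in sub.populations:
            pvals = np.minimum(pvals, hwe_pvalues(sub, sub.sample_indices(pop)))
    else:
        pvals = hwe_pvalues(sub)
    fail_hwe = pvals < hwe_p_min
    n_hwe = int(fail_hwe.sum())
    out = sub.subset_variants(~fail_hwe)

    report = QCReport(
        n_input=g.n_variants,
        n_removed_callrate=n_cr,
        n_removed_nonautosomal=n_auto,
        n_removed_maf=n_maf,
        n_removed_hwe=n_hwe,
        n_retained=out.n_variants,
        thresholds=QCThresholds(callrate_min, maf_min, hwe_p_min, autosomes),
    )
    log.info(
        "qc_filter: %d -> %d variants (callrate %d, non-autosomal %d, maf %d, hwe %d)",
        report.n_input, report.n_retained, n_cr, n_auto, n_maf, n_hwe,
    )
    return out, report
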