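"""Two-population genotype simulator with planted selective sweeps.

The generator produces the data structure the sweep scan assumes: two
populations drifted apart from a common ancestor, in Hardy–Weinberg
equilibrium within themselves, with sporadic missingness, and — inside
designated intervals — one population whose allele frequencies have been
driven toward fixation, which simultaneously depletes its nucleotide
diversity and inflates differentiation there.

The drift model is Balding–Nichols: each population's allele frequency at a
SNP is Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral frequency p, so the
expected FST between the populations is approximately F — a closed form the
test suite exploits. Inside a sweep interval the swept population draws with
the larger drift parameter ``f_sweep`` and its frequency is additionally
pushed toward the nearer boundary (0 or 1) by raising it (or its complement)
to the power ``sweep_freq_push``.

Every draw flows from a single ``numpy`` Generator seeded from
``SimParams.seed``; identical parameters give bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

log = logging.getLogger("selsig")

POP1 = "highland"
POP2 = "lowland"


@dataclass(frozen=True)
class TruthSweep:
    """A planted sweep interval (1-based inclusive bp) and the swept population."""

    chrom: str
    start: int
    end: int
    swept_pop: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"sweep start must precede end: {self}")


def _auto_sweeps(n_chrom: int, chrom_len: int, pop1: str, pop2: str
                 ) -> tuple[TruthSweep, ...]:
    """Up to six sweeps (alternating populations), one centered per chromosome.

    Each sweep spans 2 Mb, shrunk to a quarter of the chromosome when the
    chromosome cannot hold 2 Mb comfortably.
    """
    length = min(2_000_000, max(chrom_len // 4, 1) + 1)
    out = []
    for i in range(min(6, n_chrom)):
        pop = pop1 if i % 2 == 0 else pop2
        start = chrom_len // 2 - length // 2 + 1
        out.append(
            TruthSweep(chrom=str(i + 1), start=start, end=start + length - 1,
                       swept_pop=pop)
        )
    return tuple(out)


@dataclass(frozen=True)
class SimParams:
    """Simulation conditions; defaults are the package's reference scenario.

    50 + 50 samples; 18 autosomes of 40 Mb at chip-like density
    (~28 SNPs/Mb, ~20,000 SNPs genome-wide); background drift F = 0.03;
    swept-locus drift F = 0.35 with a cubic frequency push; three 2 Mb
    sweeps per population, centered on separate chromosomes
    (``sweeps=None`` auto-places them; pass an explicit tuple, possibly
    empty, to override). At a 1 Mb window and 100 kb step this genome
    yields ~7,000 windows, so a 1% quantile threshold admits a window set
    of the same order as the ~66 windows fully inside the planted sweeps —
    the regime the scan's top-fraction selection rule is designed for.
    """

    n_pop1: int = 50
    n_pop2: int = 50
    n_chrom: int = 18
    chrom_len: int = 40_000_000
    snp_density: float = 20_000 / 720_000_000
    f_background: float = 0.03
    f_sweep: float = 0.35
    sweep_freq_push: float = 3.0
    missing_rate: float = 0.02
    sweeps: tuple[TruthSweep, ...] | None = None
    pop1: str = POP1
    pop2: str = POP2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sweeps is None:
            object.__setattr__(
                self, "sweeps",
                _auto_sweeps(self.n_chrom, self.chrom_len, self.pop1, self.pop2),
            )
        if not 0 < self.f_background < 1 or not 0 < self.f_sweep < 1:
            raise ValueError("drift parameters must lie in (0, 1)")
        if self.f_sweep <= self.f_background:
            raise ValueError("f_sweep must exceed f_background")
        if self.sweep_freq_push < 1:
            raise ValueError("sweep_freq_push must be >= 1")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must lie in [0, 1]")
        chroms = {str(c + 1) for c in range(self.n_chrom)}
        by_chrom: dict[str, list[TruthSweep]] = {}
        for s in self.sweeps:
            if s.chrom not in chroms:
                raise ValueError(f"sweep chromosome {s.chrom!r} outside simulated set")
            if s.end > self.chrom_len or s.start < 1:
                raise ValueError(f"sweep {s} outside chromosome bounds")
            if s.swept_pop not in (self.pop1, self.pop2):
                raise ValueError(f"unknown swept population {s.swept_pop!r}")
            by_chrom.setdefault(s.chrom, []).append(s)
        for chrom, sw in by_chrom.items():
            sw = sorted(sw, key=lambda s: s.start)
            for a, b in zip(sw, sw[1:]):
                if b.start <= a.end:
                    raise ValueError(f"overlapping sweeps on chromosome {chrom}")


def _push_to_boundary(freq: np.ndarray, power: float) -> np.ndarray:
    """Push frequencies toward the nearer of 0/1 by exponentiation."""
    low = freq <= 0.5
    out = np.empty_like(freq)
    out[low] = freq[low] ** power
    out[~low] = 1.0 - (1.0 - freq[~low]) ** power
    return out


def simulate_genotypes(params: SimParams) -> tuple[GenotypeMatrix, list[TruthSweep]]:
    """Draw a two-population GenotypeMatrix with the planted sweeps.

    Returns the matrix (samples: pop1 block then pop2 block) and the truth
    sweep list (a copy of ``params.sweeps`` sorted by coordinate).
    """
    rng = np.random.default_rng(params.seed)
    chroms, positions = [], []
    for c in range(params.n_chrom):
        name = str(c + 1)
        n = rng.poisson(params.snp_density * params.chrom_len)
        pos = np.unique(rng.integers(1, params.chrom_len + 1, size=n))
        chroms.extend([name] * len(pos))
        positions.append(pos)
    pos_all = np.concatenate(positions) if positions else np.array([], dtype=int)
    chrom_all = np.asarray(chroms, dtype=object)
    m = len(pos_all)

    p_anc = rng.uniform(0.05, 0.95, size=m)

    # per-SNP drift parameter per population, elevated inside sweeps
    f1 = np.full(m, params.f_background)
    f2 = np.full(m, params.f_background)
    swept1 = np.zeros(m, dtype=bool)
    swept2 = np.zeros(m, dtype=bool)
    for s in params.sweeps:
        inside = (chrom_all == s.chrom) & (pos_all >= s.start) & (pos_all <= s.end)
        if s.swept_pop == params.pop1:
            f1[inside] = params.f_sweep
            swept1 |= inside
        else:
            f2[inside] = params.f_sweep
            swept2 |= inside

    def pop_freq(f: np.ndarray) -> np.ndarray:
        a = p_anc * (1.0 - f) / f
        b = (1.0 - p_anc) * (1.0 - f) / f
        return rng.beta(a, b)

    q1 = pop_freq(f1)
    q2 = pop_freq(f2)
    q1[swept1] = _push_to_boundary(q1[swept1], params.sweep_freq_push)
    q2[swept2] = _push_to_boundary(q2[swept2], params.sweep_freq_push)

    n1, n2 = params.n_pop1, params.n_pop2
    calls = np.empty((n1 + n2, m), dtype=np.int8)
    calls[:n1, :] = rng.binomial(2, q1, size=(n1, m))
    calls[n1:, :] = rng.binomial(2, q2, size=(n2, m))
    if params.missing_rate > 0:
        calls[rng.random(calls.shape) < params.missing_rate] = MISSING

    width = len(str(n1 + n2))
    samples = pd.DataFrame(
        {
            "sample_id": [f"{params.pop1}_{i + 1:0{width}d}" for i in range(n1)]
            + [f"{params.pop2}_{i + 1:0{width}d}" for i in range(n2)],
            "population": [params.pop1] * n1 + [params.pop2] * n2,
        }
    )
    variants = pd.DataFrame(
        {
            "chrom": chrom_all,
            "pos": pos_all,
            "vid": [f"snp_{c}_{p}" for c, p in zip(chrom_all, pos_all)],
            "ref": "A",
            "alt": "G",
        }
    )
    g = GenotypeMatrix(calls=calls, variants=variants, samples=samples)
    truth = sorted(params.sweeps, key=lambda s: (int(s.chrom), s.start))
    log.info("simulate_genotypes: %d SNPs, %d+%d samples, %d sweeps",
             m, n1, n2, len(truth))
    return g, truth


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeRecord:
    """Backfat (mm) and growth phenotypes for one animal.

    ``adwg`` is average daily weight gain in kg/day over the 20->50 kg
    growth interval; the two age fields are consistent with it
    (interval = 30 kg / adwg).
    """

    sample_id: str
    backfat: float
    adwg: float
    age_at_20kg: float
    age_at_50kg: float

    def __post_init__(self) -> None:
        if self.age_at_20kg <= 0 or self.age_at_50kg <= self.age_at_20kg:
            raise ValueError("ages must be positive with age_at_50kg > age_at_20kg")


#: Population means mirroring the two-trait contrast the pipeline tests:
#: (backfat mm, adwg kg/day).
DEFAULT_PHENO_MEANS: dict[str, tuple[float, float]] = {
    POP1: (14.0, 0.159),
    POP2: (18.0, 0.229),
}


def simulate_phenotypes(
    samples: pd.DataFrame,
    mean_by_pop: Mapping[str, tuple[float, float]] = None,
    sd: tuple[float, float] = (1.0, 0.02),
    seed: int = 0,
) -> list[PhenotypeRecord]:
    """Draw Normal(mean, sd) backfat and ADWG per sample, seeded.

    ``mean_by_pop`` maps population label -> (backfat mm, adwg kg/day);
    every population present in ``samples`` must have an entry. Ages are
    derived so that adwg == 30 / (age_at_50kg - age_at_20kg) exactly.
    """
    if mean_by_pop is None:
        mean_by_pop = DEFAULT_PHENO_MEANS
    pops = list(dict.fromkeys(samples["population"]))
    missing = [p for p in pops if p not in mean_by_pop]
    if missing:
        raise KeyError(f"no phenotype means for population(s): {missing}")
    rng = np.random.default_rng(seed)
    out = []
    for row in samples.itertuples(index=False):
        mu_bf, mu_adwg = mean_by_pop[row.population]
        backfat = max(0.1, mu_bf + sd[0] * rng.standard_normal())
        adwg = max(0.01, mu_adwg + sd[1] * rng.standard_normal())
        age20 = max(30.0, 100.0 + 10.0 * rng.standard_normal())
        out.append(
            PhenotypeRecord(
                sample_id=row.sample_id,
                backfat=backfat,
                adwg=adwg,
                age_at_20kg=age20,
                age_at_50kg=age20 + 30.0 / adwg,
            )
        )
    return out


def write_phenotypes(records: Sequence[PhenotypeRecord], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


# ---------------------------------------------------------------------------
# truth BED
# ---------------------------------------------------------------------------

def write_truth_bed(sweeps: Sequence[TruthSweep], path: str | Path) -> None:
    """Write planted sweeps as BED6 (0-based half-open; name = swept pop)."""
    with open(path, "w") as fh:
        for s in sweeps:
            fh.write(f"{s.chrom}\t{s.start - 1}\t{s.end}\t{s.swept_pop}\t.\t+\n")


def read_truth_bed(path: str | Path) -> list[TruthSweep]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name = line.split("\t")[:4]
            out.append(TruthSweep(chrom=chrom, start=int(start) + 1, end=int(end), swept_pop=name))
    return out
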