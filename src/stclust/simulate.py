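"""Synthetic multi-locus amplicon libraries with ground truth.

Emulates the data the genotyper is built for: per-sample libraries of
~80-1000 reads drawn from 2-12 true alleles amplifying with unequal
efficiencies, corrupted by pyrosequencing-style homopolymer indels and
substitutions, plus low-rate single-crossover PCR chimeras.  Every
emitted read carries a provenance record so genotype recovery can be
scored exactly.

Default error mix is calibrated so that 82 % of reads are error-free
(the canonical pyrosequencing figure), split in favour of homopolymer
indels, the platform's dominant error mode:
(1 - p_indel)(1 - p_sub) = 0.82 with p_indel = 0.12.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _align
from .seqprep import SampleLibrary

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated sequencing run."""

    n_samples: int = 20
    n_loci: int = 3  # diploid loci co-amplified (<= 6)
    allele_pool_size: int = 18
    allele_length: int = 213
    min_allele_divergence: float = 10.0  # percent
    n_similar_pairs: int = 1  # designated 2-bp-apart allele pairs
    library_size_range: tuple[int, int] = (80, 1000)
    p_indel: float = 0.12  # per-read homopolymer indel probability
    p_sub: float = 1.0 - 0.82 / 0.88  # per-read substitution probability
    chimera_rate: float = 0.005  # fraction of reads
    efficiency_dirichlet: float | None = None  # alpha; None = equal weights
    low_efficiency: dict[int, float] = field(default_factory=dict)
    # pool index -> relative efficiency multiplier (e.g. {0: 0.2})
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_loci <= 6):
            raise ValueError("n_loci must be between 1 and 6")
        for p in (self.p_indel, self.p_sub, self.chimera_rate):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must be in [0, 1]")
        if self.allele_length < 20:
            raise ValueError("allele_length must be >= 20")
        if self.library_size_range[0] < 1 or (
            self.library_size_range[0] > self.library_size_range[1]
        ):
            raise ValueError("invalid library_size_range")

    @property
    def error_free_fraction(self) -> float:
        return (1 - self.p_indel) * (1 - self.p_sub)


@dataclass
class ReadProvenance:
    read_index: int
    source_allele: int  # pool index; primary parent for chimeras
    events: tuple[str, ...] = ()
    chimera_parents: tuple[int, int] | None = None


@dataclass
class SampleTruth:
    sample_id: str
    true_alleles: tuple[int, ...]  # pool indices
    reads: list[ReadProvenance]
    efficiencies: dict[int, float]


@dataclass
class SimTruth:
    pool: list[str]
    samples: dict[str, SampleTruth]

    def allele_seqs(self, sample_id: str) -> set[str]:
        return {self.pool[i] for i in self.samples[sample_id].true_alleles}


# ---------------------------------------------------------------------------
# allele pool


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate_sites(seq: str, n_sites: int, rng: np.random.Generator) -> str:
    arr = bytearray(seq, "ascii")
    sites = rng.choice(len(arr), size=n_sites, replace=False)
    for p in sites:
        choices = [b for b in _BASES if b != arr[p]]
        arr[p] = int(rng.choice(choices))
    return arr.decode()


def make_allele_pool(cfg: SimConfig, rng: np.random.Generator) -> list[str]:
    """Generate an allele pool satisfying the divergence constraint.

    All pairwise similarities stay at or below
    100 - min_allele_divergence, except for the designated similar
    pairs, appended last as copies of earlier alleles with exactly two
    substitutions (emulating alleles a couple of base pairs apart).
    """
    n_base = cfg.allele_pool_size - cfg.n_similar_pairs
    if n_base < 1 or cfg.n_similar_pairs > n_base:
        raise ValueError("infeasible pool configuration")
    limit = 100.0 - cfg.min_allele_divergence
    ancestor = _random_seq(cfg.allele_length, rng)
    # substitution load per allele high enough to clear the divergence bar
    per_allele = max(1, int(np.ceil(cfg.allele_length * cfg.min_allele_divergence / 100.0 * 1.5)))
    pool: list[str] = []
    for _ in range(n_base):
        for _attempt in range(60):
            cand = _mutate_sites(ancestor, per_allele, rng)
            if all(_align.percent_similarity(cand, p) <= limit for p in pool):
                pool.append(cand)
                break
        else:
            raise RuntimeError(
                "could not satisfy allele divergence constraint; relax "
                "min_allele_divergence or shrink the pool"
            )
    for k in range(cfg.n_similar_pairs):
        twin = _mutate_sites(pool[k], 2, rng)
        while twin in pool:
            twin = _mutate_sites(pool[k], 2, rng)
        pool.append(twin)
    return pool


# ---------------------------------------------------------------------------
# read-level error model


def _homopolymer_runs(seq: str, min_len: int = 2) -> list[tuple[int, int]]:
    """(start, length) of homopolymer runs of at least ``min_len``."""
    runs = []
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            if i - start >= min_len:
                runs.append((start, i - start))
            start = i
    return runs


def apply_homopolymer_indel(seq: str, rng: np.random.Generator) -> tuple[str, str]:
    """Expand or contract one homopolymer run (length >= 2) by one base;
    returns (mutated sequence, event tag)."""
    runs = _homopolymer_runs(seq)
    if not runs:
        return seq, "indel_skipped"
    start, length = runs[rng.integers(len(runs))]
    if rng.random() < 0.5:
        return seq[:start] + seq[start] + seq[start:], f"ins@{start}"
    return seq[:start] + seq[start + 1:], f"del@{start}"


def apply_substitution(seq: str, rng: np.random.Generator) -> tuple[str, str]:
    p = int(rng.integers(len(seq)))
    old = seq[p]
    new = chr(int(rng.choice([b for b in _BASES if chr(b) != old])))
    return seq[:p] + new + seq[p + 1:], f"sub@{p}:{old}>{new}"


# ---------------------------------------------------------------------------
# sampling


def _sample_genotype(
    cfg: SimConfig, pool_size: int, rng: np.random.Generator
) -> tuple[int, ...]:
    """Draw a diploid multi-locus genotype: two allele picks per locus
    from that locus's slice of the pool; at least two distinct alleles."""
    blocks = np.array_split(np.arange(pool_size), cfg.n_loci)
    for _ in range(200):
        picked: set[int] = set()
        for block in blocks:
            picked.update(rng.choice(block, size=2, replace=True).tolist())
        if len(picked) >= 2:
            return tuple(sorted(int(i) for i in picked))
    raise RuntimeError("could not draw a genotype with >= 2 alleles")


def simulate_sample(
    pool: Sequence[str],
    cfg: SimConfig,
    rng: np.random.Generator,
    sample_id: str,
    efficiencies: dict[int, float] | None = None,
    true_alleles: Sequence[int] | None = None,
    library_size: int | None = None,
) -> tuple[SampleLibrary, SampleTruth]:
    """Simulate one sample library with per-read provenance."""
    if true_alleles is None:
        true_alleles = _sample_genotype(cfg, len(pool), rng)
    true_alleles = tuple(true_alleles)
    if efficiencies is None:
        efficiencies = {i: 1.0 for i in true_alleles}
    weights = np.array([efficiencies[i] for i in true_alleles], dtype=float)
    weights = weights / weights.sum()
    if library_size is None:
        lo, hi = cfg.library_size_range
        library_size = int(rng.integers(lo, hi + 1))

    lib = SampleLibrary(sample_id, {})
    reads: list[ReadProvenance] = []
    for r in range(library_size):
        if cfg.chimera_rate > 0 and len(true_alleles) >= 2 and rng.random() < cfg.chimera_rate:
            pa, pb = rng.choice(len(true_alleles), size=2, replace=False)
            a, b = pool[true_alleles[pa]], pool[true_alleles[pb]]
            k = int(rng.integers(1, min(len(a), len(b))))
            seq = a[:k] + b[k:]
            reads.append(
                ReadProvenance(
                    r,
                    true_alleles[pa],
                    (f"chimera@{k}",),
                    (true_alleles[pa], true_alleles[pb]),
                )
            )
        else:
            src = int(rng.choice(len(true_alleles), p=weights))
            seq = pool[true_alleles[src]]
            events: list[str] = []
            if rng.random() < cfg.p_indel:
                seq, tag = apply_homopolymer_indel(seq, rng)
                if tag != "indel_skipped":
                    events.append(tag)
            if rng.random() < cfg.p_sub:
                seq, tag = apply_substitution(seq, rng)
                events.append(tag)
            reads.append(ReadProvenance(r, true_alleles[src], tuple(events)))
        lib.add(seq)
    truth = SampleTruth(sample_id, true_alleles, reads, dict(efficiencies))
    return lib, truth


def simulate_run(cfg: SimConfig) -> tuple[dict[str, SampleLibrary], SimTruth]:
    """Simulate a whole run: allele pool, per-allele efficiencies and
    ``cfg.n_samples`` sample libraries; all randomness flows from
    ``cfg.seed``."""
    root = np.random.default_rng(cfg.seed)
    pool = make_allele_pool(cfg, root)
    if cfg.efficiency_dirichlet is not None:
        eff = root.dirichlet([cfg.efficiency_dirichlet] * len(pool)) * len(pool)
    else:
        eff = np.ones(len(pool))
    for idx, mult in cfg.low_efficiency.items():
        eff[idx] *= mult
    libs: dict[str, SampleLibrary] = {}
    samples: dict[str, SampleTruth] = {}
    for s in range(cfg.n_samples):
        sid = f"sim{s:03d}"
        rng = np.random.default_rng([cfg.seed, 1000 + s])
        genotype = _sample_genotype(cfg, len(pool), rng)
        lib, truth = simulate_sample(
            pool,
            cfg,
            rng,
            sid,
            efficiencies={i: float(eff[i]) for i in genotype},
            true_alleles=genotype,
        )
        libs[sid] = lib
        samples[sid] = truth
    return libs, SimTruth(list(pool), samples)


# ---------------------------------------------------------------------------
# recovery scoring


def recovery_report(truth: SimTruth, genotypes: Sequence) -> "pd.DataFrame":
    """Score called genotypes against the simulated truth.

    sensitivity = recovered true alleles / true alleles; false
    positives are called alleles absent from the truth.  A true allele
    with zero reads in the library counts as *missing* (unrecoverable);
    one with reads but no call counts as dropped-and-lost.
    """
    import pandas as pd

    rows = []
    for g in genotypes:
        st = truth.samples[g.sample_id]
        true_seqs = truth.allele_seqs(g.sample_id)
        called = set(g.allele_seqs)
        reads_per_allele = {i: 0 for i in st.true_alleles}
        for rp in st.reads:
            if rp.chimera_parents is None:
                reads_per_allele[rp.source_allele] += 1
        missing = {
            truth.pool[i] for i, n in reads_per_allele.items() if n == 0
        }
        recovered = called & true_seqs
        lost = true_seqs - called - missing
        rows.append(
            {
                "sample_id": g.sample_id,
                "n_true": len(true_seqs),
                "n_called": len(called),
                "n_recovered": len(recovered),
                "n_false_positive": len(called - true_seqs),
                "n_missing": len(missing),
                "n_dropped_lost": len(lost),
                "sensitivity": len(recovered) / len(true_seqs),
            }
        )
    return pd.DataFrame(rows)
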