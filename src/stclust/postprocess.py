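"""Phase 4 - post-clustering processing.

Turns per-sample cluster sets into genotypes: small clusters whose
label sequence is a common good-cluster label elsewhere are promoted to
"dropped" alleles, true alleles are screened for single-crossover PCR
chimeras, and amplification-efficiency diagnostics (drop rates, mean
relative cluster sizes and their correlation) are computed across the
run.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .stepwise import ClusterSet


class AlleleOrigin(str, Enum):
    GOOD = "good"
    DROPPED = "dropped"


@dataclass
class Genotype:
    """Per-sample set of true alleles with provenance."""

    sample_id: str
    alleles: list[tuple[str, AlleleOrigin, int]] = field(default_factory=list)
    # (sequence, origin, cluster reads)

    @property
    def allele_seqs(self) -> list[str]:
        return [seq for seq, _, _ in self.alleles]

    def __post_init__(self) -> None:
        seqs = self.allele_seqs
        if len(seqs) != len(set(seqs)):
            raise ValueError(f"{self.sample_id}: duplicate allele sequences")


# ---------------------------------------------------------------------------
# dropped-allele promotion


def promote_dropped(
    clustersets: Mapping[str, ClusterSet] | Sequence[ClusterSet],
    epsilon: int = 3,
    min_dropped_reads: int = 3,
) -> tuple[list[Genotype], pd.DataFrame]:
    """Assemble genotypes, rescuing small clusters that match common
    good clusters.

    A small cluster in sample s is promoted iff its label sequence
    labels good clusters in at least ``epsilon`` samples *other than*
    s and the cluster holds at least ``min_dropped_reads`` reads (3 by
    default; the reads need not share one sequence).  Only phase-3 good
    clusters count toward commonness - promoted alleles never bootstrap
    further promotions.

    Returns the genotypes and an allele catalog (one row per allele:
    occurrence counts, drop rate, mean relative cluster sizes).
    """
    if isinstance(clustersets, Mapping):
        csets = list(clustersets.values())
    else:
        csets = list(clustersets)

    good_samples: dict[str, set[str]] = {}
    for cs in csets:
        for c in cs.good:
            good_samples.setdefault(c.label, set()).add(cs.sample_id)

    genotypes: list[Genotype] = []
    rows: dict[str, dict] = {}

    def _note(seq: str, cs: ClusterSet, reads: int, origin: AlleleOrigin) -> None:
        row = rows.setdefault(
            seq,
            {
                "allele": seq,
                "n_samples_good": 0,
                "n_samples_dropped": 0,
                "n_samples_total": 0,
                "_rel_sizes": [],
                "_rel_sizes_good": [],
            },
        )
        row["n_samples_total"] += 1
        row["_rel_sizes"].append(reads / cs.library_size)
        if origin is AlleleOrigin.GOOD:
            row["n_samples_good"] += 1
            row["_rel_sizes_good"].append(reads / cs.library_size)
        else:
            row["n_samples_dropped"] += 1

    for cs in csets:
        geno = Genotype(cs.sample_id, [])
        seen: dict[str, int] = {}
        for c in cs.good:
            if c.label in seen:  # same label twice in one sample: merge reads
                idx = seen[c.label]
                seq, origin, reads = geno.alleles[idx]
                geno.alleles[idx] = (seq, origin, reads + c.total_reads)
                continue
            seen[c.label] = len(geno.alleles)
            geno.alleles.append((c.label, AlleleOrigin.GOOD, c.total_reads))
            _note(c.label, cs, c.total_reads, AlleleOrigin.GOOD)
        for c in cs.small:
            if c.label in seen:
                continue
            others = good_samples.get(c.label, set()) - {cs.sample_id}
            if len(others) >= epsilon and c.total_reads >= min_dropped_reads:
                seen[c.label] = len(geno.alleles)
                geno.alleles.append((c.label, AlleleOrigin.DROPPED, c.total_reads))
                _note(c.label, cs, c.total_reads, AlleleOrigin.DROPPED)
        genotypes.append(geno)

    catalog_rows = []
    for seq, row in rows.items():
        catalog_rows.append(
            {
                "allele": seq,
                "n_samples_good": row["n_samples_good"],
                "n_samples_dropped": row["n_samples_dropped"],
                "n_samples_total": row["n_samples_total"],
                "drop_rate": row["n_samples_dropped"] / row["n_samples_total"],
                "mean_relative_cluster_size": float(np.mean(row["_rel_sizes"])),
                "mean_relative_cluster_size_good": (
                    float(np.mean(row["_rel_sizes_good"]))
                    if row["_rel_sizes_good"]
                    else np.nan
                ),
            }
        )
    catalog = pd.DataFrame(
        catalog_rows,
        columns=[
            "allele",
            "n_samples_good",
            "n_samples_dropped",
            "n_samples_total",
            "drop_rate",
            "mean_relative_cluster_size",
            "mean_relative_cluster_size_good",
        ],
    ).sort_values(["n_samples_total", "allele"], ascending=[False, True], ignore_index=True)
    return genotypes, catalog


# ---------------------------------------------------------------------------
# chimera screening


def find_recombinant_candidates(
    alleles: Sequence[str],
    max_mismatch: int = 0,
) -> list[tuple[str, str, str, int]]:
    """Find alleles that look like single-crossover daughters of two
    other alleles in the same set.

    A daughter D qualifies with ordered parents (A, B) if some
    breakpoint k (both sides non-empty) splits it so that D[:k] matches
    A's prefix and D[k:] matches B's suffix with at most
    ``max_mismatch`` mismatches in total, and D differs from both
    parents.  Returns (daughter, parentA, parentB, breakpoint) for the
    smallest qualifying breakpoint of each parent pair.
    """
    out: list[tuple[str, str, str, int]] = []
    if len(alleles) < 3:
        return out
    for d, a, b in itertools.permutations(alleles, 3):
        if d == a or d == b:
            continue
        hit = _crossover_breakpoint(d, a, b, max_mismatch)
        if hit is not None:
            out.append((d, a, b, hit))
    return out


def _crossover_breakpoint(d: str, a: str, b: str, max_mismatch: int) -> int | None:
    L = len(d)
    if max_mismatch == 0:
        # longest exact prefix shared with a, longest exact suffix with b
        lcp = 0
        for x, y in zip(d, a):
            if x != y:
                break
            lcp += 1
        lcs = 0
        for x, y in zip(reversed(d), reversed(b)):
            if x != y:
                break
            lcs += 1
        lo = max(1, L - lcs)
        hi = min(L - 1, lcp)
        if lo <= hi:
            return lo
        return None
    for k in range(1, L):
        if len(a) < k or len(b) < L - k:
            continue
        mm = sum(x != y for x, y in zip(d[:k], a[:k]))
        if mm > max_mismatch:
            continue
        mm += sum(x != y for x, y in zip(d[k:], b[len(b) - (L - k):]))
        if mm <= max_mismatch:
            return k
    return None


def classify_chimeras(
    genotypes: Sequence[Genotype],
    max_mismatch: int = 0,
) -> tuple[list[Genotype], pd.DataFrame]:
    """Screen assembled genotypes for PCR chimeras.

    Each allele with at least one candidate parent pair in at least one
    sample is evaluated: over all samples containing the allele, the
    fraction in which some parent pair co-occurs is computed, and the
    allele is a chimera iff that fraction is 100 %.  Chimeras are
    removed from the returned genotypes.  The report mirrors one row
    per candidate (occurrences, occurrences with parents, percentage,
    verdict).  Order-independent in the sample order.
    """
    occurrences: dict[str, int] = {}
    with_parents: dict[str, int] = {}
    parent_pairs: dict[str, set[tuple[str, str]]] = {}
    for g in genotypes:
        seqs = g.allele_seqs
        cands = find_recombinant_candidates(seqs, max_mismatch)
        hit_here = {d for d, _, _, _ in cands}
        for seq in seqs:
            occurrences[seq] = occurrences.get(seq, 0) + 1
            if seq in hit_here:
                with_parents[seq] = with_parents.get(seq, 0) + 1
        for d, a, b, _ in cands:
            parent_pairs.setdefault(d, set()).add((a, b) if a <= b else (b, a))

    rows = []
    chimeras: set[str] = set()
    for seq in sorted(with_parents, key=lambda s: (occurrences[s], s)):
        n_occ = occurrences[seq]
        n_par = with_parents[seq]
        pct = 100.0 * n_par / n_occ
        is_chimera = pct == 100.0
        if is_chimera:
            chimeras.add(seq)
        rows.append(
            {
                "allele": seq,
                "n_occurrences": n_occ,
                "n_occurrences_with_parents": n_par,
                "percent_with_parents": pct,
                "n_parent_pairs": len(parent_pairs[seq]),
                "is_chimera": is_chimera,
            }
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "allele",
            "n_occurrences",
            "n_occurrences_with_parents",
            "percent_with_parents",
            "n_parent_pairs",
            "is_chimera",
        ],
    )
    pruned = [
        Genotype(
            g.sample_id,
            [(s, o, n) for s, o, n in g.alleles if s not in chimeras],
        )
        for g in genotypes
    ]
    return pruned, report


# ---------------------------------------------------------------------------
# optional length screen


def length_screen(
    genotypes: Sequence[Genotype],
    expected_len: int,
    enabled: bool = True,
) -> tuple[list[Genotype], list[tuple[str, str]]]:
    """Optionally remove alleles whose length differs from the expected
    amplicon length; removals are reported, never silent."""
    if not enabled:
        return list(genotypes), []
    removed: list[tuple[str, str]] = []
    out = []
    for g in genotypes:
        kept = []
        for seq, origin, n in g.alleles:
            if len(seq) == expected_len:
                kept.append((seq, origin, n))
            else:
                removed.append((g.sample_id, seq))
        out.append(Genotype(g.sample_id, kept))
    return out, removed


# ---------------------------------------------------------------------------
# diagnostics


def _pearson(x: Sequence[float], y: Sequence[float]):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return None
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def diagnostics(
    genotypes: Sequence[Genotype],
    clustersets: Mapping[str, ClusterSet] | Sequence[ClusterSet],
    min_library_sweep: Iterable[int] = (),
) -> dict:
    """Amplification-efficiency and library-size diagnostics.

    Computes per-allele drop rates and mean relative cluster sizes,
    the Pearson correlation of (drop rate, mean cluster size) over
    alleles dropped at least once, and the Pearson correlation of
    (library size, allele count) over samples, optionally re-estimated
    at increasing minimum library sizes.  Correlations with fewer than
    three points (or zero variance) are reported as None, never
    fabricated.
    """
    if isinstance(clustersets, Mapping):
        csets = {cs.sample_id: cs for cs in clustersets.values()}
    else:
        csets = {cs.sample_id: cs for cs in clustersets}

    allele_rows: dict[str, dict] = {}
    sample_rows = []
    for g in genotypes:
        cs = csets[g.sample_id]
        sample_rows.append(
            {
                "sample_id": g.sample_id,
                "library_size": cs.library_size,
                "n_alleles": len(g.alleles),
                "n_dropped": sum(
                    1 for _, o, _ in g.alleles if o is AlleleOrigin.DROPPED
                ),
            }
        )
        for seq, origin, reads in g.alleles:
            row = allele_rows.setdefault(
                seq, {"n_total": 0, "n_dropped": 0, "sizes": [], "sizes_good": []}
            )
            row["n_total"] += 1
            row["sizes"].append(reads / cs.library_size)
            if origin is AlleleOrigin.DROPPED:
                row["n_dropped"] += 1
            else:
                row["sizes_good"].append(reads / cs.library_size)

    catalog = pd.DataFrame(
        [
            {
                "allele": seq,
                "n_samples_total": row["n_total"],
                "n_samples_dropped": row["n_dropped"],
                "drop_rate": row["n_dropped"] / row["n_total"],
                "mean_relative_cluster_size": float(np.mean(row["sizes"])),
                "mean_relative_cluster_size_good": (
                    float(np.mean(row["sizes_good"])) if row["sizes_good"] else np.nan
                ),
            }
            for seq, row in allele_rows.items()
        ]
    )
    samples = pd.DataFrame(
        sample_rows,
        columns=["sample_id", "library_size", "n_alleles", "n_dropped"],
    )
    if catalog.empty:
        catalog = pd.DataFrame(
            columns=[
                "allele",
                "n_samples_total",
                "n_samples_dropped",
                "drop_rate",
                "mean_relative_cluster_size",
                "mean_relative_cluster_size_good",
            ]
        )

    dropped = catalog[catalog["n_samples_dropped"] > 0]
    drop_corr = _pearson(
        dropped["drop_rate"].tolist(),
        dropped["mean_relative_cluster_size"].tolist(),
    )
    size_corr = _pearson(
        samples["library_size"].tolist(), samples["n_alleles"].tolist()
    )
    sweep = {}
    for lo in min_library_sweep:
        sub = samples[samples["library_size"] >= lo]
        sweep[int(lo)] = _pearson(
            sub["library_size"].tolist(), sub["n_alleles"].tolist()
        )
    return {
        "allele_catalog": catalog,
        "samples": samples,
        "drop_rate_vs_cluster_size": drop_corr,
        "library_size_vs_allele_count": size_corr,
        "library_size_sweep": sweep,
    }


# ---------------------------------------------------------------------------
# outputs


def assemble_outputs(
    genotypes: Sequence[Genotype],
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Build the samples x alleles presence/absence matrix and a stable
    allele id list (ordered by total occurrence, then sequence)."""
    totals: dict[str, int] = {}
    for g in genotypes:
        for seq in g.allele_seqs:
            totals[seq] = totals.get(seq, 0) + 1
    ordered = sorted(totals, key=lambda s: (-totals[s], s))
    ids = [(f"allele_{i + 1:04d}", seq) for i, seq in enumerate(ordered)]
    id_of = {seq: aid for aid, seq in ids}
    data = {
        g.sample_id: {id_of[seq]: 1 for seq in g.allele_seqs} for g in genotypes
    }
    matrix = (
        pd.DataFrame.from_dict(data, orient="index", dtype="Int64")
        .reindex(columns=[aid for aid, _ in ids])
        .fillna(0)
        .astype(int)
    )
    matrix.index.name = "sample_id"
    return matrix.sort_index(), ids


def write_allele_fasta(ids: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for aid, seq in ids:
            fh.write(f">{aid}\n{seq}\n")
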