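"""Phase 2 - sequence combination.

Length-variant artifacts (dominated by homopolymer over/under-calls in
pyrosequencing data) carry information about the alleles they derive
from.  This phase classifies every pair of unique sequences in a sample
library into five types by their alignment difference profile and
converts the reads of clearly derived, wrong-length members into reads
of their correct-length source sequence:

    type I    exactly one indel, no substitutions
    type II   one insertion and one deletion, no substitutions
    type III  one indel and one substitution
    type IV   one indel and two substitutions
    type V    everything else - never combined

Combination requires (1) a first member of the expected amplicon
length, (2) the first member strictly more common than the second, and
(3) an unambiguous derivation: a second member shared by several pairs
of one type is, by default, combined with the most common candidate
first member (the behaviour of the published worked example); strict
mode refuses such pairs entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

from . import _align
from .seqprep import SampleLibrary


class PairType(str, Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"


@dataclass(frozen=True)
class PairDiff:
    """Difference profile of one aligned sequence pair.

    ``n_insertions`` counts alignment columns with a base only in
    ``seq_b``; ``n_deletions`` columns with a base only in ``seq_a``;
    a run of k gap columns counts as k indels.
    """

    seq_a: str
    seq_b: str
    n_insertions: int
    n_deletions: int
    n_substitutions: int
    n_matches: int

    @property
    def n_indels(self) -> int:
        return self.n_insertions + self.n_deletions

    @property
    def pair_type(self) -> PairType:
        return _pair_type(self.n_insertions, self.n_deletions, self.n_substitutions)


@dataclass(frozen=True)
class CombineRecord:
    absorbed_seq: str
    target_seq: str
    pair_type: PairType
    reads_moved: int


def _pair_type(n_ins: int, n_del: int, n_sub: int) -> PairType:
    indels = n_ins + n_del
    if indels == 1 and n_sub == 0:
        return PairType.I
    if n_ins == 1 and n_del == 1 and n_sub == 0:
        return PairType.II
    if indels == 1 and n_sub == 1:
        return PairType.III
    if indels == 1 and n_sub == 2:
        return PairType.IV
    return PairType.V


def align_and_diff(a: str, b: str) -> PairDiff:
    """Globally align two sequences under the package's fixed scoring and
    return their indel/substitution profile."""
    matches, subs, only_a, only_b = _align.nw_counts(a, b)
    return PairDiff(a, b, n_insertions=only_b, n_deletions=only_a,
                    n_substitutions=subs, n_matches=matches)


def classify_pair(
    diff: PairDiff,
    count_a: int,
    count_b: int,
    expected_len: int,
) -> tuple[PairType, str | None, str | None]:
    """Return (pair_type, first, second) with members ordered for
    combination.

    For types I/III/IV the first member is the sequence of the expected
    length; if neither or both members have it the pair is demoted to
    type V.  For type II (equal lengths, required to equal the expected
    length) the first member is the more common sequence; an exact
    read-count tie leaves the pair unordered (type V).
    """
    ptype = diff.pair_type
    a, b = diff.seq_a, diff.seq_b
    if ptype in (PairType.I, PairType.III, PairType.IV):
        a_ok = len(a) == expected_len
        b_ok = len(b) == expected_len
        if a_ok == b_ok:  # neither or both: not combinable
            return PairType.V, None, None
        return (ptype, a, b) if a_ok else (ptype, b, a)
    if ptype is PairType.II:
        if len(a) != expected_len:  # equal lengths by construction
            return PairType.V, None, None
        if count_a == count_b:
            return PairType.V, None, None
        return (ptype, a, b) if count_a > count_b else (ptype, b, a)
    return PairType.V, None, None


_COMBINE_ORDER = (PairType.I, PairType.II, PairType.III, PairType.IV)


def combine_library(
    lib: SampleLibrary,
    expected_len: int,
    strict: bool = False,
) -> tuple[SampleLibrary, list[CombineRecord]]:
    """Combine derived length-variant sequences into their sources.

    Types are processed in order I -> II -> III -> IV, recomputing the
    pair profiles against the current library state between types.
    Total read count is conserved; the number of unique sequences never
    increases.  ``strict=True`` skips any second member shared by
    several candidate pairs of one type instead of resolving toward the
    most common first member.
    """
    if expected_len <= 0:
        raise ValueError("expected_len must be positive")
    counts = dict(lib.counts)
    records: list[CombineRecord] = []
    for ptype in _COMBINE_ORDER:
        seqs = sorted(counts)
        # candidate (second -> list of firsts) under the current state
        candidates: dict[str, list[str]] = {}
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                a, b = seqs[i], seqs[j]
                diff = align_and_diff(a, b)
                t, first, second = classify_pair(diff, counts[a], counts[b], expected_len)
                if t is not ptype or first is None:
                    continue
                if counts[first] <= counts[second]:
                    continue
                candidates.setdefault(second, []).append(first)
        # resolve shared second members, then apply deterministically
        plan: list[tuple[str, str]] = []
        for second in sorted(candidates, key=lambda s: (-counts[s], s)):
            firsts = candidates[second]
            if len(firsts) > 1:
                if strict:
                    continue
                firsts = sorted(firsts, key=lambda s: (-counts[s], s))
                top, runner = counts[firsts[0]], counts[firsts[1]]
                if top == runner:  # exact tie between candidate sources
                    continue
            plan.append((second, firsts[0]))
        for second, first in plan:
            if second not in counts or first not in counts:
                continue
            if counts[first] <= counts[second]:  # re-validated at absorption
                continue
            moved = counts.pop(second)
            counts[first] += moved
            records.append(CombineRecord(second, first, ptype, moved))
    return SampleLibrary(lib.sample_id, counts), records


def records_to_tsv(
    records: Iterable[tuple[str, CombineRecord]] | Iterable[CombineRecord],
    path: str | Path,
    sample_id: str | None = None,
) -> None:
    """Write combination records as TSV (sample, absorbed, target, type,
    reads_moved)."""
    with open(path, "w") as fh:
        fh.write("sample_id\tabsorbed\ttarget\tpair_type\treads_moved\n")
        for item in records:
            if isinstance(item, CombineRecord):
                sid, rec = sample_id or "", item
            else:
                sid, rec = item
            fh.write(
                f"{sid}\t{rec.absorbed_seq}\t{rec.target_seq}\t"
                f"{rec.pair_type.value}\t{rec.reads_moved}\n"
            )
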