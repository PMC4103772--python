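"""Synthetic worked-example fixture.

A deterministic, programmatically constructed sample library (plus
three companion libraries) that exercises every pathway of the
genotyper the way a real single-sample walkthrough would: six true
alleles including a pair two base pairs apart, wrong-length artifacts
of combination types I-IV, a rare divergent allele that drops out in
phase 3 and is rescued by cross-checking, and a rare artifact that is
not.  All sequences are synthetic; expected milestones are derived
from the construction itself and validated at build time, so the
fixture doubles as its own oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import _align
from .seqprep import SampleLibrary
from .simulate import _homopolymer_runs, _mutate_sites, _random_seq

FIXTURE_SEED = 20_1407
EXPECTED_LEN = 213


@dataclass(frozen=True)
class WorkedExample:
    """The fixture and the milestones implied by its construction."""

    library: SampleLibrary  # the focal sample ("sample_x")
    companions: dict[str, SampleLibrary]  # samples sharing the dropped allele
    alleles: dict[str, str]  # role -> sequence (b1..b4, s1, s2, dropped)
    artifact_small: str  # rare sequence promoted nowhere
    n_unique_initial: int
    n_unique_after: dict[str, int]  # pair type -> uniques after that type
    total_reads: int
    combined_per_type: dict[str, int]
    # phase-3/4 expectations
    end_good: int = 4
    end_small: int = 2
    end_ambiguous: int = 1
    final_good: int = 6
    final_alleles: int = 7


def _del_in_run(seq: str, which: int = 0) -> str:
    runs = _homopolymer_runs(seq)
    start, _ = runs[which % len(runs)]
    return seq[:start] + seq[start + 1:]


def _ins_in_run(seq: str, which: int = 0) -> str:
    runs = _homopolymer_runs(seq)
    start, _ = runs[which % len(runs)]
    return seq[:start] + seq[start] + seq[start:]


def _sub_at(seq: str, pos: int) -> str:
    order = "ACGT"
    new = order[(order.index(seq[pos]) + 1) % 4]
    return seq[:pos] + new + seq[pos + 1:]


@lru_cache(maxsize=1)
def worked_example() -> WorkedExample:
    rng = np.random.default_rng(FIXTURE_SEED)
    ancestor = _random_seq(EXPECTED_LEN, rng)

    def make(load: int) -> str:
        return _mutate_sites(ancestor, load, rng)

    # six true alleles: four well separated, one close pair (2 bp apart)
    b1, b2, b3, b4 = (make(14) for _ in range(4))
    s1 = make(14)
    s2 = _mutate_sites(s1, 2, rng)
    dropped = make(55)  # divergent, low-read allele shared with companions
    artifact = make(55)  # divergent rare artifact unique to the sample

    alleles = {"b1": b1, "b2": b2, "b3": b3, "b4": b4, "s1": s1, "s2": s2,
               "dropped": dropped}

    # wrong-length / same-length artifacts to be combined in phase 2
    t1 = {_del_in_run(b1, 0): 8, _ins_in_run(b2, 1): 6, _del_in_run(s1, 2): 4}
    t2 = {_ins_in_run(_del_in_run(b3, 0), 5): 3}
    t3 = {_sub_at(_del_in_run(b1, 3), 150): 3, _sub_at(_ins_in_run(b4, 4), 40): 2}
    t4 = {_sub_at(_sub_at(_del_in_run(b2, 6), 30), 120): 2}

    # s1 is the library's most common sequence, so the close pair's
    # cluster keeps s1 as its label and survives to the final round as
    # the one residual ambiguous cluster (85 vs 35 reads after phase 2)
    counts: dict[str, int] = {
        b1: 62, b2: 45, b3: 41, b4: 31, s1: 81, s2: 35,
        dropped: 4, artifact: 3,
    }
    for d in (t1, t2, t3, t4):
        counts.update(d)
    if len(counts) != 8 + 7:
        raise AssertionError("fixture sequences collide; construction invalid")

    lib = SampleLibrary("sample_x", counts)
    if lib.library_size != 330:
        raise AssertionError("fixture read total drifted")

    # construction sanity: similarity structure the walkthrough relies on
    core = [b1, b2, b3, b4, s1, s2]
    for i, a in enumerate(core):
        for bseq in core[i + 1:]:
            sim = _align.percent_similarity(a, bseq)
            if (a, bseq) == (s1, s2):
                continue
            if {a, bseq} == {s1, s2}:
                continue
            if not (75.0 <= sim <= 94.0):
                raise AssertionError(f"allele similarity {sim:.1f} out of band")
    if _align.percent_similarity(s1, s2) < 98.0:
        raise AssertionError("similar pair drifted apart")
    for rare in (dropped, artifact):
        for a in core:
            if _align.percent_similarity(rare, a) > 84.0:
                raise AssertionError("rare sequence too similar to an allele")

    companions = {
        f"companion{i}": SampleLibrary(
            f"companion{i}", {dropped: 60, core[i]: 40}
        )
        for i in range(3)
    }

    combined = {"I": len(t1), "II": len(t2), "III": len(t3), "IV": len(t4)}
    n0 = lib.n_unique
    after = {
        "I": n0 - combined["I"],
        "II": n0 - combined["I"] - combined["II"],
        "III": n0 - combined["I"] - combined["II"] - combined["III"],
        "IV": 8,
    }
    return WorkedExample(
        library=lib,
        companions=companions,
        alleles=alleles,
        artifact_small=artifact,
        n_unique_initial=n0,
        n_unique_after=after,
        total_reads=330,
        combined_per_type=combined,
    )


def load_fixture(name: str) -> SampleLibrary:
    """Load a packaged fixture library by name.

    ``worked_example`` is the focal synthetic sample;
    ``worked_example/companionN`` (N = 0..2) are its companions.  A
    user-supplied sequence-count table can be loaded instead with
    :meth:`stclust.seqprep.SampleLibrary.from_tsv`.
    """
    wx = worked_example()
    if name == "worked_example":
        return wx.library
    if name.startswith("worked_example/"):
        key = name.split("/", 1)[1]
        if key in wx.companions:
            return wx.companions[key]
    raise KeyError(
        f"unknown fixture {name!r}; available: worked_example, "
        + ", ".join(f"worked_example/{k}" for k in wx.companions)
    )
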