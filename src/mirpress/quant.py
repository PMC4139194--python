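"""Small-RNA quantification against mature miRNA references.

Reads are assigned directly to mature reference sequences with a 5'-anchored,
gapless comparison: up to two mismatches are tolerated within reference
positions 1-17, any number from position 18 onward, and up to four
non-templated 3' overhang nucleotides are ignored.  Counts are normalized to
reads per million (RPM) using either the total of miRNA-mapped reads or an
externally supplied per-library genome-mapped total, and guide/passenger
(star) arms are called from the arm-abundance ratio of each hairpin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

RNA_ALPHABET = frozenset("ACGU")
#: nucleotides accepted in reads; N never matches a reference base
READ_ALPHABET = frozenset("ACGUN")

#: reference positions 1..CORE_LEN form the mismatch-limited core
CORE_LEN = 17
MAX_CORE_MISMATCHES = 2
#: read 3' nucleotides beyond the reference end are treated as
#: non-templated additions up to this length; longer overhangs reject
MAX_OVERHANG = 4

DENOMINATOR_MODES = ("mirna_mapped", "genome_mapped")
MULTIMAP_POLICIES = ("fractional", "all")


def canonical_rna(seq: str, *, allow_n: bool = False) -> str:
    """Uppercase a nucleotide string and convert DNA T to RNA U.

    Raises ``ValueError`` for empty input or characters outside the RNA
    alphabet (plus N when *allow_n* is set).
    """
    if not seq:
        raise ValueError("empty sequence")
    out = seq.upper().replace("T", "U")
    allowed = READ_ALPHABET if allow_n else RNA_ALPHABET
    bad = set(out) - allowed
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return out


@dataclass(frozen=True)
class MatureReference:
    """A mature miRNA reference sequence from one arm of a hairpin."""

    name: str
    hairpin: str
    arm: str  # "5p" or "3p"
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", canonical_rna(self.sequence))
        if len(self.sequence) < CORE_LEN:
            raise ValueError(
                f"{self.name}: mature sequence shorter than {CORE_LEN} nt"
            )
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"{self.name}: arm must be '5p' or '3p', got {self.arm!r}")


@dataclass(frozen=True)
class MatchResult:
    """Outcome of aligning one read against one mature reference."""

    accepted: bool
    mismatches: tuple[int, ...] = ()  # 1-based reference positions
    core_mismatches: int = 0
    overhang: int = 0


def match_read(read: str, ref: MatureReference) -> MatchResult:
    """Score a read against a mature reference, 5'-anchored and gapless.

    The read is aligned to the reference 5' end.  Mismatches within
    reference positions 1-17 are counted and the read is accepted when
    there are at most two; positions 18 onward are unconstrained.  Read
    bases extending past the reference 3' end are ignored up to
    ``MAX_OVERHANG`` nucleotides.  N in the read mismatches everything.
    """
    read = canonical_rna(read, allow_n=True)
    if len(read) < CORE_LEN:
        return MatchResult(accepted=False)
    overhang = len(read) - len(ref.sequence)
    if overhang > MAX_OVERHANG:
        return MatchResult(accepted=False, overhang=overhang)
    span = min(len(read), len(ref.sequence))
    mismatches = tuple(
        i + 1
        for i in range(span)
        if read[i] != ref.sequence[i] or read[i] == "N"
    )
    core = sum(1 for p in mismatches if p <= CORE_LEN)
    return MatchResult(
        accepted=core <= MAX_CORE_MISMATCHES,
        mismatches=mismatches,
        core_mismatches=core,
        overhang=max(overhang, 0),
    )


def _is_blacklisted(read: str, blacklist: Sequence[str]) -> bool:
    return any(read in bl for bl in blacklist)


def quantify(
    reads_by_replicate: Mapping[str, Iterable[str] | Mapping[str, int]] | Iterable[str],
    refs: Sequence[MatureReference],
    blacklist: Sequence[str] = (),
    policy: str = "fractional",
) -> pd.DataFrame:
    """Count reads per mature reference for one or more replicates.

    Each replicate is an iterable of read sequences or a pre-collapsed
    mapping of read sequence to multiplicity.  Reads exactly contained in
    any blacklist sequence (tRNA/rRNA filter) are discarded.  Each
    surviving read is scored against every reference with
    :func:`match_read`; a read accepted by k references contributes 1/k of
    its multiplicity to each under the default ``fractional`` policy, or
    the full multiplicity to each under ``all``.  Returns a DataFrame
    indexed by mature name with one column per replicate.
    """
    from collections import Counter

    if not refs:
        raise ValueError("reference set is empty")
    if policy not in MULTIMAP_POLICIES:
        raise ValueError(f"unknown multimap policy {policy!r}")
    if not isinstance(reads_by_replicate, Mapping):
        # a bare iterable of reads is a single replicate
        reads_by_replicate = {"rep1": reads_by_replicate}
    elif reads_by_replicate and all(
        isinstance(v, (int, float)) for v in reads_by_replicate.values()
    ):
        # a single collapsed read -> multiplicity mapping
        reads_by_replicate = {"rep1": reads_by_replicate}
    bl = tuple(canonical_rna(s) for s in blacklist)
    names = [r.name for r in refs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate mature reference names")
    # reads repeat heavily; memoize the per-read assignment vector
    cache: dict[str, tuple[str, ...]] = {}
    columns: dict[str, dict[str, float]] = {}
    for rep, reads in reads_by_replicate.items():
        collapsed = (
            Counter(dict(reads)) if isinstance(reads, Mapping) else Counter(reads)
        )
        acc = {name: 0.0 for name in names}
        for raw, mult in collapsed.items():
            read = canonical_rna(raw, allow_n=True)
            hits = cache.get(read)
            if hits is None:
                if _is_blacklisted(read, bl):
                    hits = ()
                else:
                    hits = tuple(
                        r.name for r in refs if match_read(read, r).accepted
                    )
                cache[read] = hits
            if not hits:
                continue
            inc = mult / len(hits) if policy == "fractional" else float(mult)
            for name in hits:
                acc[name] += inc
        columns[rep] = acc
    counts = pd.DataFrame(columns, index=pd.Index(names, name="mirna"))
    return counts[list(reads_by_replicate)]


@dataclass
class ExpressionProfile:
    """Per-miRNA expression: raw counts, per-replicate RPM, mean and SD."""

    counts: pd.DataFrame
    rpm: pd.DataFrame
    mean_rpm: pd.Series
    sd_rpm: pd.Series
    totals: pd.Series
    denominator_mode: str

    @property
    def replicates(self) -> list[str]:
        return list(self.counts.columns)

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.add_prefix("count_").join(self.rpm.add_prefix("rpm_"))
        out["mean_rpm"] = self.mean_rpm
        out["sd_rpm"] = self.sd_rpm
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, denominator_mode: str = "mirna_mapped"):
        counts = frame[[c for c in frame.columns if c.startswith("count_")]].rename(
            columns=lambda c: c[len("count_"):]
        )
        rpm = frame[[c for c in frame.columns if c.startswith("rpm_")]].rename(
            columns=lambda c: c[len("rpm_"):]
        )
        return cls(
            counts=counts,
            rpm=rpm,
            mean_rpm=frame["mean_rpm"],
            sd_rpm=frame["sd_rpm"],
            totals=counts.sum(axis=0),
            denominator_mode=denominator_mode,
        )


def normalize_rpm(
    counts: pd.DataFrame,
    denominator_mode: str = "mirna_mapped",
    external_totals: Mapping[str, float] | None = None,
) -> ExpressionProfile:
    """Normalize raw counts to reads per million.

    Under ``mirna_mapped`` (default) the per-replicate denominator is the
    total count assigned to mature miRNAs, so each replicate's RPM column
    sums to 1e6.  Under ``genome_mapped`` the caller supplies per-replicate
    genome-mapped totals as *external_totals*.
    """
    if denominator_mode not in DENOMINATOR_MODES:
        raise ValueError(f"unknown denominator mode {denominator_mode!r}")
    if denominator_mode == "genome_mapped":
        if external_totals is None:
            raise ValueError("genome_mapped mode requires external_totals")
        denom = pd.Series(
            {rep: float(external_totals[rep]) for rep in counts.columns}
        )
    else:
        denom = counts.sum(axis=0)
    if (denom <= 0).any():
        bad = list(denom.index[denom <= 0])
        raise ValueError(f"zero/negative normalization denominator for {bad}")
    rpm = counts * 1e6 / denom
    sd = rpm.std(axis=1, ddof=1)
    if rpm.shape[1] == 1:
        sd = sd.fillna(0.0)
    return ExpressionProfile(
        counts=counts,
        rpm=rpm,
        mean_rpm=rpm.mean(axis=1),
        sd_rpm=sd,
        totals=counts.sum(axis=0),
        denominator_mode=denominator_mode,
    )


@dataclass(frozen=True)
class ArmCall:
    """Guide/star assignment for one hairpin."""

    hairpin: str
    dominant_arm: str  # mature name of the more abundant arm
    star_arm: str | None  # mature name of the minor arm, if called star
    ratio: float  # high / low abundance, >= 1


def classify_arms(
    mean_rpm: pd.Series | ExpressionProfile,
    pairing: Sequence[tuple[str, str, str]],
    ratio_threshold: float = 4.0,
) -> list[ArmCall]:
    """Call star arms where the arm-abundance ratio strictly exceeds 4:1.

    *pairing* lists (hairpin, name_5p, name_3p).  A mature name absent from
    the profile is treated as abundance 0.  A ratio exactly equal to the
    threshold does not produce a star call; when the minor arm has zero
    abundance and the major does not, the ratio is infinite and the minor
    arm is the star.
    """
    if isinstance(mean_rpm, ExpressionProfile):
        mean_rpm = mean_rpm.mean_rpm
    calls = []
    for hairpin, name5, name3 in pairing:
        a5 = float(mean_rpm.get(name5, 0.0))
        a3 = float(mean_rpm.get(name3, 0.0))
        if a5 >= a3:
            dominant, minor, hi, lo = name5, name3, a5, a3
        else:
            dominant, minor, hi, lo = name3, name5, a3, a5
        if hi == 0.0:
            ratio = 1.0  # both undetected: no evidence either way
        elif lo == 0.0:
            ratio = math.inf
        else:
            ratio = hi / lo
        star = minor if ratio > ratio_threshold else None
        calls.append(ArmCall(hairpin=hairpin, dominant_arm=dominant, star_arm=star, ratio=ratio))
    return calls


def arm_calls_to_frame(calls: Sequence[ArmCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "hairpin": c.hairpin,
                "dominant_arm": c.dominant_arm,
                "star_arm": c.star_arm if c.star_arm is not None else "",
                "ratio": c.ratio,
            }
            for c in calls
        ]
    )
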