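"""Canonical 7-nt seed-site prediction and target-site abundance.

A target-side seed motif is the reverse complement of miRNA positions 2-8
(1-based from the 5' end).  UTRs are scanned for exact motif occurrences on
the sense strand; per-gene counts take the maximum over that gene's UTR
isoforms, and target-site abundance (TSA) weights those maxima by mRNA
expression.  Reporter cloning junctions (insert plus 6 nt of vector flank on
each side) are screened for adventitious sites created for other miRNAs,
whose summed expression gives the additive-expression estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .quant import canonical_rna

SEED_START = 1  # 0-based: miRNA positions 2-8
SEED_END = 8
FLANK_LEN = 6


@dataclass(frozen=True)
class SeedMotif:
    """Target-side motif: reverse complement of miRNA seed (positions 2-8)."""

    mirna: str
    motif: str  # 7 nt, RNA alphabet, target strand 5'->3'

    @property
    def motif_dna(self) -> str:
        return self.motif.replace("U", "T")


def seed_motif(mature: str, name: str = "") -> SeedMotif:
    """Derive the 7-nt target-side seed motif from a mature miRNA sequence."""
    seq = canonical_rna(mature)
    if len(seq) < SEED_END:
        raise ValueError(f"mature sequence shorter than {SEED_END} nt")
    seed = seq[SEED_START:SEED_END]
    motif = str(Seq(seed).reverse_complement_rna())
    return SeedMotif(mirna=name, motif=motif)


def scan_sequence(seq: str, motif: SeedMotif | str) -> list[int]:
    """All overlapping exact occurrences of the motif, 0-based starts.

    The sequence may be DNA or RNA and may contain N, which never matches.
    """
    pattern = motif.motif if isinstance(motif, SeedMotif) else str(motif)
    pattern = canonical_rna(pattern)
    target = seq.upper().replace("T", "U")
    hits = []
    start = 0
    while True:
        i = target.find(pattern, start)
        if i == -1:
            return hits
        hits.append(i)
        start = i + 1


def gene_site_counts(
    utrs: Iterable[tuple[str, str, str]],
    motifs: Sequence[SeedMotif],
) -> pd.DataFrame:
    """Maximal per-gene seed-site count for each miRNA over UTR isoforms.

    *utrs* yields (gene, utr_id, sequence).  When a gene has several UTR
    isoforms the per-isoform site counts are combined by taking the maximum.
    Returns a DataFrame indexed by gene with one integer column per miRNA.
    """
    rows: dict[str, dict[str, int]] = {}
    seen_utrs: set[str] = set()
    for gene, utr_id, seq in utrs:
        if utr_id in seen_utrs:
            raise ValueError(f"duplicate UTR id {utr_id!r}")
        seen_utrs.add(utr_id)
        counts = rows.setdefault(gene, {m.mirna: 0 for m in motifs})
        for m in motifs:
            n = len(scan_sequence(seq, m))
            if n > counts[m.mirna]:
                counts[m.mirna] = n
    out = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    out.index.name = "gene"
    return out.reindex(columns=[m.mirna for m in motifs], fill_value=0)


def target_site_abundance(
    site_counts: pd.DataFrame,
    mrna_expression: Mapping[str, float] | pd.Series,
) -> pd.Series:
    """TSA(m) = sum over genes of expression(gene) * max site count(m, gene).

    Genes without an expression value contribute 0 (with a warning);
    negative expression is an error.
    """
    expr = pd.Series(dict(mrna_expression), dtype=float)
    if (expr < 0).any():
        raise ValueError("negative mRNA expression values")
    missing = [g for g in site_counts.index if g not in expr.index]
    if missing:
        warnings.warn(
            f"{len(missing)} gene(s) without expression values treated as 0",
            stacklevel=2,
        )
    weights = expr.reindex(site_counts.index).fillna(0.0)
    tsa = site_counts.mul(weights, axis=0).sum(axis=0)
    tsa.name = "target_site_abundance"
    return tsa


@dataclass
class JunctionReport:
    """Adventitious-site screen of one reporter cloning junction."""

    construct: str
    sequence: str  # upstream flank + insert + downstream flank
    designed: str
    matches: list[tuple[str, int]] = field(default_factory=list)
    additive_expression: float = 0.0

    @property
    def matching_mirnas(self) -> list[str]:
        seen: list[str] = []
        for name, _ in self.matches:
            if name not in seen:
                seen.append(name)
        return seen


def junction_scan(
    insert: str,
    upstream_flank: str,
    downstream_flank: str,
    all_motifs: Sequence[SeedMotif],
    mean_rpm: Mapping[str, float] | pd.Series,
    designed: str = "",
    construct: str | None = None,
    include_designed: bool = True,
    allow_flank_length_mismatch: bool = False,
) -> JunctionReport:
    """Scan insert-with-flanks for every miRNA's seed motif on the sense strand.

    Flanks must be exactly 6 nt of vector context unless explicitly
    overridden.  ``additive_expression`` sums each matching miRNA's mean
    RPM once, regardless of how many sites it matches; the designed miRNA
    is included by default.
    """
    if not allow_flank_length_mismatch and (
        len(upstream_flank) != FLANK_LEN or len(downstream_flank) != FLANK_LEN
    ):
        raise ValueError(
            f"flanks must be exactly {FLANK_LEN} nt "
            "(pass allow_flank_length_mismatch=True to override)"
        )
    region = upstream_flank + insert + downstream_flank
    matches: list[tuple[str, int]] = []
    for m in all_motifs:
        for pos in scan_sequence(region, m):
            matches.append((m.mirna, pos))
    rpm = pd.Series(dict(mean_rpm), dtype=float) if not isinstance(mean_rpm, pd.Series) else mean_rpm
    total = 0.0
    counted: set[str] = set()
    for name, _ in matches:
        if name in counted:
            continue
        if name == designed and not include_designed:
            continue
        counted.add(name)
        total += float(rpm.get(name, 0.0))
    return JunctionReport(
        construct=construct if construct is not None else designed,
        sequence=region,
        designed=designed,
        matches=sorted(matches, key=lambda t: (t[1], t[0])),
        additive_expression=total,
    )


def junction_reports_to_frame(reports: Sequence[JunctionReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "construct": r.construct,
                "designed": r.designed,
                "n_matches": len(r.matches),
                "matching_mirnas": ",".join(r.matching_mirnas),
                "additive_expression": r.additive_expression,
            }
            for r in reports
        ]
    ).set_index("construct")
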