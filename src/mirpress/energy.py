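"""Duplex free energy of a miRNA paired to its exact reverse complement.

Reporter target sites are perfect complements of the mature miRNA, so the
minimum-free-energy structure of the miRNA:target duplex is the fully paired
helix.  Its free energy is the closed-form nearest-neighbor sum: helix
initiation plus one stacking term per adjacent base pair plus a penalty for
each terminal A:U pair, using a bundled published RNA/RNA parameter table.
Dangling-end and self-complementarity terms are omitted.  Absolute values
therefore need not match any particular folding program; the scale supports
relative comparisons (more negative = more stable).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from .quant import canonical_rna

DEFAULT_PARAMETER_SET = "xia1998"


@lru_cache(maxsize=None)
def load_parameters(parameter_set: str = DEFAULT_PARAMETER_SET) -> dict:
    """Load a bundled nearest-neighbor parameter table by id."""
    ref = resources.files("mirpress.data") / f"nn_rna_{parameter_set}.json"
    try:
        return json.loads(ref.read_text())
    except FileNotFoundError:
        raise ValueError(f"unknown parameter set {parameter_set!r}") from None


@dataclass(frozen=True)
class DuplexScore:
    mirna: str
    delta_g: float  # kcal/mol; negative = stable
    gc_fraction: float
    parameter_set: str


def gc_content(seq: str) -> float:
    """Fraction of G and C nucleotides in a non-empty sequence."""
    s = canonical_rna(seq, allow_n=True)
    return (s.count("G") + s.count("C")) / len(s)


def duplex_mfe(
    mature: str,
    name: str = "",
    parameter_set: str = DEFAULT_PARAMETER_SET,
) -> DuplexScore:
    """Free energy of the fully paired miRNA:target helix.

    The target is the exact reverse complement of the mature sequence
    (the reporter design), so every position is a Watson-Crick pair and
    the nearest-neighbor sum runs over the miRNA strand's dinucleotides.
    """
    seq = canonical_rna(mature)
    if len(seq) < 2:
        raise ValueError("duplex requires at least 2 paired nucleotides")
    params = load_parameters(parameter_set)
    stacks = params["stacks"]
    dg = params["initiation"]
    for i in range(len(seq) - 1):
        dg += stacks[seq[i : i + 2]]
    for end in (seq[0], seq[-1]):
        if end in "AU":
            dg += params["terminal_au_penalty"]
    return DuplexScore(
        mirna=name,
        delta_g=round(dg, 10),
        gc_fraction=gc_content(seq),
        parameter_set=params["id"],
    )
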