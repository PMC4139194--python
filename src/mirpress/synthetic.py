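"""Synthetic miRNA panels, luciferase plates, Ago-1 counts and UTR sets.

Every downstream stage of the pipeline can be exercised against data with
known ground truth.  The generator emulates the study conditions the
pipeline is built for: a panel of hairpins contributing one 5p and one 3p
mature sequence each, with abundances tiling 5-6 orders of magnitude;
percent repression following a log-linear law in log10 RPM (slope ~10 per
decade, ceiling 80%) with Gaussian noise calibrated so the log-scale
Pearson correlation lands near 0.7; dual-luciferase plates with
multiplicative day-level (transfection) noise and a small per-well noise on
the Renilla channel; Ago-1 counts tracking cellular counts in log space
with noise calibrated to r ~ 0.98; and UTR sets with seed sites planted at
known positions, where rejection sampling forbids accidental matches so the
planted-site ledger is an exact oracle.

All distributional choices here are package conventions for testing, not
claims about any particular experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .energy import duplex_mfe
from .luciferase import EMPTY_ID
from .quant import MatureReference
from .targets import scan_sequence, seed_motif

_NT = np.array(list("ACGU"))

#: default log10-RPM range tiled by a panel (5-6 orders of magnitude)
DEFAULT_LOG10_RPM_RANGE = (0.0, 6.0)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth generator parameters for recovery tests.

    ``noise_sd_repression`` and ``occupancy_log_sd`` defaults were chosen by
    Monte-Carlo calibration so that, on 32-miRNA panels tiling six decades,
    the median log-scale expression-repression Pearson r is ~0.71 and the
    median cell-vs-Ago log-log r is ~0.98.
    """

    slope: float = 10.4  # % repression per decade of expression
    intercept: float = 10.0  # % repression at 1 RPM
    noise_sd_repression: float = 19.0  # %
    luciferase_day_cv: float = 0.05  # day-level multiplicative noise, fraction
    luciferase_well_cv: float = 0.01  # per-well Renilla noise, fraction
    occupancy_log_sd: float = 0.35  # log10 units
    ago_log_offset: float = 0.0  # log10 units, constant RISC-loading offset
    ceiling: float = 80.0  # maximum achievable repression, %
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("slope", "noise_sd_repression", "luciferase_day_cv",
                     "luciferase_well_cv", "occupancy_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not all(map(math.isfinite, (self.slope, self.intercept, self.ceiling))):
            raise ValueError("truth parameters must be finite")


@dataclass
class SyntheticPanel:
    """A set of hairpins, each contributing a 5p and a 3p mature sequence."""

    mirnas: list[MatureReference]
    true_rpm: dict[str, float]
    hairpin_pairs: list[tuple[str, str, str]]  # (hairpin, name_5p, name_3p)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.mirnas]

    def sequence_of(self, name: str) -> str:
        for m in self.mirnas:
            if m.name == name:
                return m.sequence
        raise KeyError(name)

    def rpm_series(self) -> pd.Series:
        return pd.Series(self.true_rpm, name="true_rpm").loc[self.names]


def _random_mature(rng: np.random.Generator, used_seeds: set[str]) -> str:
    """A random 21-23 nt RNA whose seed 7-mer is unseen in the panel."""
    while True:
        length = int(rng.integers(21, 24))
        seq = "".join(rng.choice(_NT, size=length))
        seed7 = seq[1:8]
        if seed7 not in used_seeds:
            used_seeds.add(seed7)
            return seq


def _stratified_log10(rng: np.random.Generator, n: int, lo: float, hi: float) -> np.ndarray:
    """One uniform draw per equal-width stratum of [lo, hi], shuffled.

    Stratification tiles the range, guaranteeing the abundance span: for
    n >= 32 values on [0, 6] the max/min RPM ratio is at least 1e5.
    """
    edges = np.linspace(lo, hi, n + 1)
    vals = edges[:-1] + rng.random(n) * np.diff(edges)
    rng.shuffle(vals)
    return vals


def gen_panel(
    n_hairpins: int,
    seed: int,
    log10_rpm_range: tuple[float, float] = DEFAULT_LOG10_RPM_RANGE,
    allow_shared_seeds: bool = False,
) -> SyntheticPanel:
    """Generate ``n_hairpins`` hairpins (2 mature sequences each).

    Abundances tile the configured log10-RPM range; mature sequences are
    pairwise dissimilar (no shared seed 7-mer) unless *allow_shared_seeds*.
    """
    if n_hairpins < 1:
        raise ValueError("n_hairpins must be >= 1")
    rng = np.random.default_rng(seed)
    used: set[str] = set()
    mirnas: list[MatureReference] = []
    pairs: list[tuple[str, str, str]] = []
    for i in range(1, n_hairpins + 1):
        hp = f"syn-mir-{i:03d}"
        for arm in ("5p", "3p"):
            name = f"{hp}-{arm}"
            seq = (
                "".join(rng.choice(_NT, size=int(rng.integers(21, 24))))
                if allow_shared_seeds
                else _random_mature(rng, used)
            )
            mirnas.append(MatureReference(name=name, hairpin=hp, arm=arm, sequence=seq))
        pairs.append((hp, f"{hp}-5p", f"{hp}-3p"))
    lo, hi = log10_rpm_range
    log_rpm = _stratified_log10(rng, 2 * n_hairpins, lo, hi)
    true_rpm = {m.name: float(10.0 ** v) for m, v in zip(mirnas, log_rpm)}
    return SyntheticPanel(mirnas=mirnas, true_rpm=true_rpm, hairpin_pairs=pairs)


def gen_true_repression(
    panel: SyntheticPanel,
    truth: SyntheticTruth,
    stability_effect: float = 0.0,
) -> dict[str, float]:
    """True percent repression from the log-linear law plus Gaussian noise.

    repression_i = clamp(intercept + slope*log10(rpm_i) + eps_i, 0, ceiling).
    A non-zero *stability_effect* adds that many percent repression per
    standard deviation of (positive) duplex free energy across the panel,
    planting the weaker-duplex -> more-repression-per-copy coupling for
    sign-recovery tests.
    """
    rng = np.random.default_rng(truth.rng_seed)
    names = panel.names
    log_rpm = np.array([math.log10(panel.true_rpm[n]) for n in names])
    eps = rng.normal(0.0, truth.noise_sd_repression, size=len(names))
    vals = truth.intercept + truth.slope * log_rpm + eps
    if stability_effect != 0.0:
        dg = np.array([duplex_mfe(panel.sequence_of(n)).delta_g for n in names])
        z = (dg - dg.mean()) / dg.std() if dg.std() > 0 else np.zeros_like(dg)
        vals = vals + stability_effect * z
    vals = np.clip(vals, 0.0, truth.ceiling)
    return {n: float(v) for n, v in zip(names, vals)}


def gen_luciferase(
    repression: Mapping[str, float],
    days: int,
    truth: SyntheticTruth,
    seed: int,
    base_firefly: float = 1e5,
    base_ratio: float = 2.0,
) -> pd.DataFrame:
    """Raw dual-luciferase plate values for each construct and day.

    Firefly carries day-level multiplicative (transfection) noise; Renilla
    is firefly * base_ratio * (1 - repression/100) times a small per-well
    multiplicative noise.  An empty-vector construct with repression 0 is
    always included.  Day-level noise cancels in the per-day empty-vector
    normalization, so recovery error is governed by ``luciferase_well_cv``.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    bad = [c for c, r in repression.items() if not 0.0 <= r <= 100.0]
    if bad:
        raise ValueError(f"repression outside [0, 100] for {bad}")
    rng = np.random.default_rng(seed)
    sigma_day = math.sqrt(math.log1p(truth.luciferase_day_cv ** 2))
    sigma_well = math.sqrt(math.log1p(truth.luciferase_well_cv ** 2))
    constructs = [EMPTY_ID, *repression.keys()]
    repr_map = {EMPTY_ID: 0.0, **dict(repression)}
    rows = []
    for d in range(1, days + 1):
        day_factor = float(rng.lognormal(0.0, sigma_day))
        for c in constructs:
            firefly = base_firefly * day_factor * float(rng.lognormal(0.0, sigma_day))
            renilla = (
                firefly
                * base_ratio
                * (1.0 - repr_map[c] / 100.0)
                * float(rng.lognormal(0.0, sigma_well))
            )
            rows.append(
                {"construct": c, "day": f"day{d}", "renilla": renilla, "firefly": firefly}
            )
    return pd.DataFrame(rows)


def gen_ago_counts(
    panel: SyntheticPanel, truth: SyntheticTruth, seed: int
) -> pd.DataFrame:
    """Ago-1-associated RPM tracking cellular RPM in log space.

    log10(ago_rpm) = log10(cell_rpm) + offset + Normal(0, occupancy_log_sd).
    """
    rng = np.random.default_rng(seed)
    names = panel.names
    log_cell = np.array([math.log10(panel.true_rpm[n]) for n in names])
    log_ago = log_cell + truth.ago_log_offset + rng.normal(
        0.0, truth.occupancy_log_sd, size=len(names)
    )
    return pd.DataFrame(
        {"cell_rpm": 10.0 ** log_cell, "ago_rpm": 10.0 ** log_ago},
        index=pd.Index(names, name="mirna"),
    )


def gen_read_counts(
    panel: SyntheticPanel,
    depth: int,
    seed: int,
    abundance: Mapping[str, float] | None = None,
    sampling: str = "multinomial",
) -> dict[str, int]:
    """Per-miRNA emitted read counts at a sequencing depth.

    ``multinomial`` draws one library of *depth* reads; ``poisson`` draws
    independent Poisson counts with the same expectations; ``exact``
    deterministically rounds depth * relative abundance (zero-noise
    emission).  Abundance defaults to the panel's ``true_rpm``.
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    rng = np.random.default_rng(seed)
    names = panel.names
    weights = np.array(
        [(abundance or panel.true_rpm)[n] for n in names], dtype=float
    )
    p = weights / weights.sum()
    if sampling == "multinomial":
        counts = rng.multinomial(depth, p)
    elif sampling == "poisson":
        counts = rng.poisson(depth * p)
    elif sampling == "exact":
        counts = np.round(depth * p).astype(int)
    else:
        raise ValueError(f"unknown sampling mode {sampling!r}")
    return {n: int(k) for n, k in zip(names, counts)}


def gen_reads(
    panel: SyntheticPanel,
    n_reads: int,
    seed: int,
    abundance: Mapping[str, float] | None = None,
    sampling: str = "multinomial",
) -> tuple[list[str], dict[str, int]]:
    """Emit reads as exact copies of mature sequences.

    Returns the shuffled read list and the ledger of emitted copies per
    miRNA (the quantification oracle).
    """
    counts = gen_read_counts(panel, n_reads, seed, abundance, sampling)
    rng = np.random.default_rng(seed + 1)
    reads: list[str] = []
    for name, k in counts.items():
        reads.extend([panel.sequence_of(name)] * k)
    rng.shuffle(reads)
    return reads, counts


def collapsed_reads(panel: SyntheticPanel, counts: Mapping[str, int]) -> dict[str, int]:
    """Ledger counts keyed by read sequence (collapsed-FASTA form)."""
    out: dict[str, int] = {}
    for name, k in counts.items():
        if k > 0:
            seq = panel.sequence_of(name)
            out[seq] = out.get(seq, 0) + int(k)
    return out


# ---------------------------------------------------------------------------
# UTR sets with planted seed sites
# ---------------------------------------------------------------------------

@dataclass
class UtrSet:
    utrs: list[tuple[str, str, str]]  # (gene, utr_id, sequence)
    expression: pd.Series  # gene -> mRNA expression level
    ledger: pd.DataFrame  # gene, utr_id, mirna, start (0-based)

    def ledger_max_counts(self) -> pd.DataFrame:
        """Per-gene maximal planted-site count per miRNA (the scan oracle)."""
        if self.ledger.empty:
            genes = sorted({g for g, _, _ in self.utrs})
            return pd.DataFrame(index=pd.Index(genes, name="gene"))
        per_utr = (
            self.ledger.groupby(["gene", "utr_id", "mirna"]).size().rename("n")
        )
        return (
            per_utr.groupby(["gene", "mirna"]).max().unstack(fill_value=0)
        )


def _motif_free_background(
    rng: np.random.Generator, length: int, motifs: Sequence[str]
) -> str:
    """Random sequence containing no occurrence of any motif.

    Windows containing a motif are resampled until the sequence is clean.
    """
    seq = list(rng.choice(_NT, size=length))
    for _ in range(1000):
        text = "".join(seq)
        hit = -1
        for m in motifs:
            i = text.find(m)
            if i != -1:
                hit = i
                break
        if hit == -1:
            return text
        for j in range(hit, min(hit + 7, length)):
            seq[j] = str(rng.choice(_NT))
    raise RuntimeError("could not generate motif-free background")


def gen_utr_set(
    panel: SyntheticPanel,
    n_genes: int,
    site_rate: float,
    seed: int,
    utr_length: int = 400,
    isoforms: int = 1,
) -> UtrSet:
    """UTRs with Poisson(site_rate) seed sites planted per gene per miRNA.

    Backgrounds are rejection-sampled to contain no accidental seed match
    for any panel miRNA, and planting is re-attempted whenever a planted
    motif creates a spurious match of another motif across a boundary, so
    the returned ledger records exactly the sites a scanner should find.
    """
    if site_rate < 0:
        raise ValueError("site_rate must be non-negative")
    rng = np.random.default_rng(seed)
    motifs = [seed_motif(m.sequence, m.name) for m in panel.mirnas]
    motif_strs = [m.motif for m in motifs]
    utrs: list[tuple[str, str, str]] = []
    ledger_rows: list[dict] = []
    for g in range(1, n_genes + 1):
        gene = f"gene{g:04d}"
        for iso in range(1, isoforms + 1):
            utr_id = f"{gene}|utr{iso}"
            for _attempt in range(100):
                bg = _motif_free_background(rng, utr_length, motif_strs)
                plan: list[tuple[str, str]] = []  # (mirna, motif)
                for m in motifs:
                    k = int(rng.poisson(site_rate))
                    plan.extend([(m.mirna, m.motif)] * k)
                # choose non-overlapping 7-nt slots
                positions: list[int] = []
                ok = True
                for _name, _motif in plan:
                    for _ in range(200):
                        p = int(rng.integers(0, utr_length - 6))
                        if all(abs(p - q) >= 7 for q in positions):
                            positions.append(p)
                            break
                    else:
                        ok = False
                        break
                if not ok:
                    continue
                seq = list(bg)
                for (name, motif), p in zip(plan, positions):
                    seq[p : p + 7] = motif
                text = "".join(seq)
                # verify: planting must not spawn extra matches of any motif
                expected: dict[str, int] = {m.mirna: 0 for m in motifs}
                for (name, _motif), _p in zip(plan, positions):
                    expected[name] += 1
                if all(
                    len(scan_sequence(text, m)) == expected[m.mirna] for m in motifs
                ):
                    utrs.append((gene, utr_id, text))
                    for (name, _motif), p in zip(plan, positions):
                        ledger_rows.append(
                            {"gene": gene, "utr_id": utr_id, "mirna": name, "start": p}
                        )
                    break
            else:
                raise RuntimeError(f"could not plant sites for {utr_id}")
    expression = pd.Series(
        rng.lognormal(mean=3.0, sigma=1.0, size=n_genes),
        index=pd.Index([f"gene{g:04d}" for g in range(1, n_genes + 1)], name="gene"),
        name="expression",
    )
    ledger = pd.DataFrame(ledger_rows, columns=["gene", "utr_id", "mirna", "start"])
    return UtrSet(utrs=utrs, expression=expression, ledger=ledger)


# ---------------------------------------------------------------------------
# Study-scale synthetic stand-in
# ---------------------------------------------------------------------------

@dataclass
class StudyLikeDataset:
    """Synthetic stand-in for the study-scale 32-miRNA reporter panel.

    The raw measurements behind the published panel are not redistributed
    with this package, so study-scale checks run against this synthetic
    dataset instead.  Its ground truth encodes the qualitative facts the
    study reports: five low-abundance constructs with no true repression,
    a ~50-fold bantam arm ratio with the minor arm the stronger repressor,
    a pair of equally expressed miRNAs whose repression differs by >40%,
    a pair repressing equally despite a >100-fold expression gap, and top
    abundances whose repression saturates below the 80% ceiling.
    """

    panel: SyntheticPanel
    truth: SyntheticTruth
    true_repression: dict[str, float]
    null_constructs: tuple[str, ...]


_STUDY_HAIRPINS = (
    "bantam", "let-7", "miR-307a", "miR-308", "miR-317", "miR-986",
    "miR-996", "miR-1", "miR-252", "miR-970", "miR-1003", "miR-34",
    "miR-184", "miR-33", "miR-8", "miR-79",
)

_NULLS = ("let-7-3p", "miR-307a-5p", "miR-970-5p", "miR-1003-5p", "miR-34-3p")

#: scripted (log10 RPM, true repression %) anchors; remaining arms tile the
#: gap between the null tier and the abundant tier along the log-linear law
_STUDY_ANCHORS: dict[str, tuple[float, float]] = {
    "let-7-3p": (0.30, 0.0),
    "miR-307a-5p": (0.50, 0.0),
    "miR-970-5p": (0.70, 0.0),
    "miR-1003-5p": (0.40, 0.0),
    "miR-34-3p": (0.60, 0.0),
    "bantam-3p": (6.00, 72.0),
    "bantam-5p": (4.30, 78.0),
    "miR-184-3p": (5.60, 74.0),
    "miR-33-5p": (5.20, 70.0),
    "miR-8-3p": (5.40, 73.0),
    "miR-1-3p": (4.50, 50.0),
    "miR-252-5p": (2.00, 48.0),
    "miR-996-3p": (3.00, 65.0),
    "miR-986-5p": (3.10, 20.0),
}


def study_like_panel(seed: int = 0) -> StudyLikeDataset:
    """Build the synthetic study-scale panel (16 hairpins, 32 matures).

    Anchored miRNAs take their scripted abundance and repression; the
    remaining arms tile log10 RPM on [1, 5] with repression from the
    log-linear law (slope 10.4, intercept 10) plus Normal(0, 6) noise,
    floored at 10% so that every non-null construct is a true repressor.
    """
    rng = np.random.default_rng(seed)
    used: set[str] = set()
    mirnas: list[MatureReference] = []
    pairs: list[tuple[str, str, str]] = []
    for hp in _STUDY_HAIRPINS:
        for arm in ("5p", "3p"):
            name = f"{hp}-{arm}"
            mirnas.append(
                MatureReference(
                    name=name, hairpin=hp, arm=arm,
                    sequence=_random_mature(rng, used),
                )
            )
        pairs.append((hp, f"{hp}-5p", f"{hp}-3p"))
    truth = SyntheticTruth(rng_seed=seed)
    names = [m.name for m in mirnas]
    free = [n for n in names if n not in _STUDY_ANCHORS]
    tiled = np.linspace(1.0, 5.0, len(free))
    order = rng.permutation(len(free))
    log_rpm: dict[str, float] = {n: v for n, (v, _r) in _STUDY_ANCHORS.items()}
    repression: dict[str, float] = {n: r for n, (_v, r) in _STUDY_ANCHORS.items()}
    for idx, n in zip(order, free):
        x = float(tiled[idx])
        log_rpm[n] = x
        law = truth.intercept + truth.slope * x + rng.normal(0.0, 6.0)
        repression[n] = float(np.clip(law, 10.0, truth.ceiling))
    true_rpm = {n: float(10.0 ** log_rpm[n]) for n in names}
    panel = SyntheticPanel(mirnas=mirnas, true_rpm=true_rpm, hairpin_pairs=pairs)
    return StudyLikeDataset(
        panel=panel,
        truth=truth,
        true_repression={n: repression[n] for n in names},
        null_constructs=_NULLS,
    )
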