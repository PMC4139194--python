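"""Formats, configuration and pipeline orchestration.

TSV (tab-separated, header row, ``#`` comment lines) is the interchange
format for all tables; FASTA/FASTQ are read through Biopython with
transparent gzip support.  Small-RNA read files may be collapsed FASTA
(``>id_xN`` headers carrying multiplicities).  ``run_pipeline`` binds the
stages — quantification, repression, target/junction scans, duplex scoring,
model fitting, occupancy — into one deterministic run, and ``simulate``
writes a complete synthetic input bundle plus a ready-to-run config.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq

from . import __version__
from .luciferase import (
    EMPTY_ID,
    PLATE_COLUMNS,
    RepressionResult,
    count_nonsignificant,
    repression_from_raw,
    results_to_frame,
)
from .model import (
    DEFAULT_PSEUDOCOUNT,
    FitResult,
    OccupancyResult,
    expression_corrected_repression,
    fit_loglinear,
    fit_to_frame,
    occupancy_analysis,
    pearson_linear,
    refit_excluding,
)
from .energy import duplex_mfe
from .quant import (
    ArmCall,
    ExpressionProfile,
    MatureReference,
    arm_calls_to_frame,
    classify_arms,
    normalize_rpm,
    quantify,
)
from .targets import (
    JunctionReport,
    gene_site_counts,
    junction_reports_to_frame,
    junction_scan,
    scan_sequence,
    seed_motif,
    target_site_abundance,
)

logger = logging.getLogger("mirpress")

_COLLAPSED = re.compile(r"_x(\d+)$")


# ---------------------------------------------------------------------------
# FASTA / FASTQ / TSV
# ---------------------------------------------------------------------------

def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA/FASTQ file, gzip transparent."""
    path = Path(path)
    fmt = "fastq" if ".fastq" in path.name or ".fq" in path.name else "fasta"
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, fmt)]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def read_reads(path: str | Path) -> dict[str, int]:
    """Reads as a sequence -> multiplicity mapping.

    Collapsed-FASTA headers ending in ``_xN`` contribute N copies;
    other records contribute 1 each.
    """
    out: dict[str, int] = {}
    for rid, seq in read_fasta(path):
        m = _COLLAPSED.search(rid)
        out[seq] = out.get(seq, 0) + (int(m.group(1)) if m else 1)
    return out


def write_reads(counts: Mapping[str, int], path: str | Path) -> None:
    """Write a read -> multiplicity mapping as collapsed FASTA."""
    with open(path, "w") as fh:
        for i, (seq, n) in enumerate(counts.items(), start=1):
            fh.write(f">read{i}_x{n}\n{seq}\n")


def write_table(
    df: pd.DataFrame | pd.Series,
    path: str | Path,
    config_hash: str | None = None,
) -> None:
    """Write a TSV with a comment header carrying version and config hash."""
    if isinstance(df, pd.Series):
        df = df.to_frame()
    with open(path, "w") as fh:
        fh.write(f"# mirpress {__version__}\n")
        if config_hash:
            fh.write(f"# config_hash {config_hash}\n")
        df.to_csv(fh, sep="\t", index=df.index.name is not None or df.index.nlevels > 1)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_mature_fasta(
    path: str | Path, pairing: Sequence[tuple[str, str, str]] | None = None
) -> list[MatureReference]:
    """Mature references from FASTA; hairpin/arm resolved from the pairing
    table when given, otherwise from the ``-5p``/``-3p`` name suffix.

    Mixed case and DNA T are canonicalized to uppercase RNA.
    """
    arm_of: dict[str, tuple[str, str]] = {}
    if pairing:
        for hp, n5, n3 in pairing:
            arm_of[n5] = (hp, "5p")
            arm_of[n3] = (hp, "3p")
    refs = []
    for name, seq in read_fasta(path):
        if name in arm_of:
            hp, arm = arm_of[name]
        elif name.endswith(("-5p", "-3p")):
            hp, arm = name[:-3], name[-2:]
        else:
            hp, arm = name, "5p"
        refs.append(MatureReference(name=name, hairpin=hp, arm=arm, sequence=seq))
    return refs


def read_pairing(path: str | Path) -> list[tuple[str, str, str]]:
    df = read_table(path)
    missing = {"hairpin", "name_5p", "name_3p"} - set(df.columns)
    if missing:
        raise ValueError(f"pairing table missing columns: {sorted(missing)}")
    return list(df[["hairpin", "name_5p", "name_3p"]].itertuples(index=False, name=None))


def read_utrs(path: str | Path, sep: str = "|") -> list[tuple[str, str, str]]:
    """(gene, utr_id, sequence) triples; FASTA headers are ``gene|utr_id``."""
    out = []
    for rid, seq in read_fasta(path):
        gene = rid.split(sep, 1)[0]
        out.append((gene, rid, seq))
    return out


def read_expression(path: str | Path) -> pd.Series:
    df = read_table(path)
    if df.shape[1] < 2:
        raise ValueError("expression table needs gene and value columns")
    return df.set_index(df.columns[0]).iloc[:, 0].astype(float)


def read_plates(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    days_with_empty = set(df.loc[df["construct"] == EMPTY_ID, "day"])
    missing_days = sorted(set(df["day"]) - days_with_empty)
    if missing_days:
        raise ValueError(
            f"plate table lacks an {EMPTY_ID!r} record on day(s) {missing_days}"
        )
    return df


def read_constructs(path: str | Path) -> pd.DataFrame:
    """Reporter construct table: mirna, mature_sequence, target_with_flanks."""
    df = read_table(path)
    missing = {"mirna", "mature_sequence", "target_with_flanks"} - set(df.columns)
    if missing:
        raise ValueError(f"construct table missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Paths and parameters for one reproducible pipeline run."""

    refs_fasta: str
    pairing_tsv: str
    reads_fastas: dict[str, str]  # replicate id -> path
    plates_tsv: str
    utr_fasta: str
    mrna_expression_tsv: str
    constructs_tsv: str
    outdir: str
    blacklist_fasta: str | None = None
    ago_reads_fastas: dict[str, str] = field(default_factory=dict)
    denominator_mode: str = "mirna_mapped"
    genome_totals: dict[str, float] = field(default_factory=dict)
    ago_genome_totals: dict[str, float] = field(default_factory=dict)
    multimap_policy: str = "fractional"
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    alpha: float = 0.05
    star_ratio_threshold: float = 4.0
    rng_seed: int = 0
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        path_fields = [
            "refs_fasta", "pairing_tsv", "plates_tsv", "utr_fasta",
            "mrna_expression_tsv", "constructs_tsv",
        ]
        for f in path_fields:
            p = getattr(self, f)
            if not Path(p).exists():
                raise ValueError(f"config field {f}: path does not exist: {p}")
        for rep, p in {**self.reads_fastas, **self.ago_reads_fastas}.items():
            if not Path(p).exists():
                raise ValueError(
                    f"config field reads_fastas[{rep}]: path does not exist: {p}"
                )
        if self.blacklist_fasta and not Path(self.blacklist_fasta).exists():
            raise ValueError(
                f"config field blacklist_fasta: path does not exist: {self.blacklist_fasta}"
            )
        if not self.reads_fastas:
            raise ValueError("config field reads_fastas: at least one replicate required")
        if not 0 < self.alpha < 1:
            raise ValueError("config field alpha must be in (0, 1)")
        if self.pseudocount < 0:
            raise ValueError("config field pseudocount must be non-negative")
        if self.star_ratio_threshold < 1:
            raise ValueError("config field star_ratio_threshold must be >= 1")

    def hash(self) -> str:
        """Short digest of the config, excluding the output location."""
        payload = asdict(self)
        payload.pop("outdir")
        return hashlib.sha1(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    profile: ExpressionProfile
    arm_calls: list[ArmCall]
    repression: list[RepressionResult]
    site_counts: pd.DataFrame
    tsa: pd.Series
    junctions: list[JunctionReport]
    duplex: pd.DataFrame
    fits: dict[str, FitResult]
    corrected_repression: pd.Series
    correlations: dict[str, float]
    occupancy: OccupancyResult | None


def _quantify_stage(config: RunConfig, refs, blacklist, reads_paths, totals, label):
    reads = {rep: read_reads(p) for rep, p in reads_paths.items()}
    counts = quantify(reads, refs, blacklist=blacklist, policy=config.multimap_policy)
    profile = normalize_rpm(
        counts,
        denominator_mode=config.denominator_mode,
        external_totals=totals or None,
    )
    logger.info("%s: %d reads assigned over %d replicates", label,
                int(profile.totals.sum()), len(reads_paths))
    return profile


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute quant -> repression -> targets/junctions -> duplex -> model.

    Writes all result tables (TSV with config-hash headers) plus a
    human-readable ``summary.txt`` into ``config.outdir``.  Fully
    deterministic given the config.
    """
    config.validate()
    chash = config.hash()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("quant")
        pairing = read_pairing(config.pairing_tsv)
        refs = read_mature_fasta(config.refs_fasta, pairing)
        blacklist = (
            [s for _, s in read_fasta(config.blacklist_fasta)]
            if config.blacklist_fasta
            else []
        )
        profile = _quantify_stage(
            config, refs, blacklist, config.reads_fastas, config.genome_totals, "cell"
        )
        arm_calls = classify_arms(profile, pairing, config.star_ratio_threshold)
        write_table(profile.to_frame(), outdir / "expression_profile.tsv", chash)
        write_table(
            arm_calls_to_frame(arm_calls).set_index("hairpin"),
            outdir / "arm_calls.tsv", chash,
        )
    except Exception as e:
        raise RuntimeError(f"[quant] {e}") from e

    try:
        stage("repression")
        plates = read_plates(config.plates_tsv)
        repression = repression_from_raw(plates, alpha=config.alpha)
        rep_frame = results_to_frame(repression)
        write_table(rep_frame, outdir / "repression.tsv", chash)
    except Exception as e:
        raise RuntimeError(f"[repression] {e}") from e

    try:
        stage("targets")
        motifs = [seed_motif(r.sequence, r.name) for r in refs]
        utrs = read_utrs(config.utr_fasta)
        site_counts = gene_site_counts(utrs, motifs)
        mrna_expr = read_expression(config.mrna_expression_tsv)
        tsa = target_site_abundance(site_counts, mrna_expr)
        write_table(site_counts, outdir / "site_counts.tsv", chash)
        write_table(tsa.rename_axis("mirna"), outdir / "target_site_abundance.tsv", chash)
    except Exception as e:
        raise RuntimeError(f"[targets] {e}") from e

    try:
        stage("junctions")
        constructs = read_constructs(config.constructs_tsv)
        junctions = []
        for row in constructs.itertuples(index=False):
            twf = row.target_with_flanks
            junctions.append(
                junction_scan(
                    insert=twf[6:-6],
                    upstream_flank=twf[:6],
                    downstream_flank=twf[-6:],
                    all_motifs=motifs,
                    mean_rpm=profile.mean_rpm,
                    designed=row.mirna,
                )
            )
        write_table(junction_reports_to_frame(junctions), outdir / "junctions.tsv", chash)
    except Exception as e:
        raise RuntimeError(f"[junctions] {e}") from e

    try:
        stage("duplex")
        scores = [duplex_mfe(r.sequence, r.name) for r in refs]
        duplex = pd.DataFrame(
            {
                "delta_g": [s.delta_g for s in scores],
                "gc_fraction": [s.gc_fraction for s in scores],
                "parameter_set": [s.parameter_set for s in scores],
            },
            index=pd.Index([s.mirna for s in scores], name="mirna"),
        )
        write_table(duplex, outdir / "duplex.tsv", chash)
    except Exception as e:
        raise RuntimeError(f"[duplex] {e}") from e

    try:
        stage("model")
        rep_pct = rep_frame.loc[rep_frame.index != EMPTY_ID, "repression_pct"]
        shared = profile.mean_rpm.index.intersection(rep_pct.index)
        expr = profile.mean_rpm.loc[shared]
        rep_shared = rep_pct.loc[shared]
        fits: dict[str, FitResult] = {}
        fits["all"] = fit_loglinear(expr, rep_shared, config.pseudocount)
        _, nonsig = count_nonsignificant(repression)
        if len(shared) - len(set(nonsig) & set(shared)) >= 3:
            fits["excluding_nonsignificant"] = refit_excluding(
                expr, rep_shared, nonsig, config.pseudocount
            )
        corrected = expression_corrected_repression(rep_shared, expr, config.pseudocount)
        correlations = {"pearson_r_linear": pearson_linear(expr, rep_shared)}
        dsub = duplex.loc[shared]
        valid = corrected.notna()
        if valid.sum() >= 3:
            from scipy import stats as _stats

            correlations["r_deltag_corrected"] = float(
                _stats.pearsonr(dsub.loc[valid, "delta_g"], corrected[valid]).statistic
            )
            correlations["r_gc_corrected"] = float(
                _stats.pearsonr(dsub.loc[valid, "gc_fraction"], corrected[valid]).statistic
            )
            tsa_shared = tsa.reindex(shared).fillna(0.0)
            if tsa_shared[valid].nunique() > 1:
                correlations["r_tsa_corrected"] = float(
                    _stats.pearsonr(tsa_shared[valid], corrected[valid]).statistic
                )
        occupancy = None
        if config.ago_reads_fastas:
            ago_profile = _quantify_stage(
                config, refs, blacklist, config.ago_reads_fastas,
                config.ago_genome_totals, "ago",
            )
            occupancy = occupancy_analysis(
                profile.mean_rpm, ago_profile.mean_rpm, rep_pct, config.pseudocount
            )
            write_table(occupancy.records, outdir / "occupancy.tsv", chash)
        write_table(fit_to_frame(fits), outdir / "fits.tsv", chash)
        write_table(
            corrected.rename_axis("mirna"), outdir / "corrected_repression.tsv", chash
        )
    except Exception as e:
        raise RuntimeError(f"[model] {e}") from e

    result = PipelineResult(
        profile=profile,
        arm_calls=arm_calls,
        repression=repression,
        site_counts=site_counts,
        tsa=tsa,
        junctions=junctions,
        duplex=duplex,
        fits=fits,
        corrected_repression=corrected,
        correlations=correlations,
        occupancy=occupancy,
    )
    _write_summary(result, nonsig, outdir / "summary.txt", chash)
    if config.make_plots:
        _write_plots(result, outdir, config.pseudocount)
    return result


def _write_summary(result: PipelineResult, nonsig, path: Path, chash: str) -> None:
    fit = result.fits["all"]
    lines = [
        f"# mirpress {__version__} (config {chash})",
        f"miRNAs profiled: {len(result.profile.mean_rpm)}",
        f"constructs assayed: {len(result.repression) - 1}",
        f"log-linear fit: slope {fit.slope:.2f}%/decade "
        f"(95% CI {fit.ci_lo:.2f}..{fit.ci_hi:.2f}), intercept {fit.intercept:.2f}%, "
        f"r(log) = {fit.pearson_r:.3f}, n = {fit.n}",
        f"r(linear RPM) = {result.correlations['pearson_r_linear']:.3f}",
        f"non-significant constructs ({len(nonsig)}): {', '.join(nonsig) or 'none'}",
        f"star arms called: "
        f"{sum(1 for c in result.arm_calls if c.star_arm is not None)}",
    ]
    if "excluding_nonsignificant" in result.fits:
        f2 = result.fits["excluding_nonsignificant"]
        lines.append(
            f"fit excluding non-significant: slope {f2.slope:.2f}%/decade, "
            f"r = {f2.pearson_r:.3f}, n = {f2.n}"
        )
    for key in ("r_deltag_corrected", "r_gc_corrected", "r_tsa_corrected"):
        if key in result.correlations:
            lines.append(f"{key} = {result.correlations[key]:.3f}")
    if result.occupancy is not None:
        lines.append(f"r(log cell, log Ago-1) = {result.occupancy.r_cell_ago:.3f}")
        if result.occupancy.r_ago_repression is not None:
            lines.append(
                f"r(log Ago-1, repression) = {result.occupancy.r_ago_repression:.3f}"
            )
    path.write_text("\n".join(lines) + "\n")


def _write_plots(result: PipelineResult, outdir: Path, pseudocount: float) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rep = results_to_frame(result.repression)
    rep = rep.loc[rep.index != EMPTY_ID, "repression_pct"]
    shared = result.profile.mean_rpm.index.intersection(rep.index)
    x = np.log10(result.profile.mean_rpm.loc[shared] + pseudocount)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, rep.loc[shared])
    fit = result.fits["all"]
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, fit.intercept + fit.slope * xs, "k-")
    ax.set_xlabel("log10 mean RPM")
    ax.set_ylabel("repression (%)")
    fig.tight_layout()
    fig.savefig(outdir / "expression_vs_repression.png", dpi=120)
    plt.close(fig)
    if result.occupancy is not None:
        rec = result.occupancy.records
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(
            np.log10(rec["cell_rpm"] + pseudocount),
            np.log10(rec["ago_rpm"] + pseudocount),
        )
        ax.set_xlabel("log10 cell RPM")
        ax.set_ylabel("log10 Ago-1 RPM")
        fig.tight_layout()
        fig.savefig(outdir / "cell_vs_ago.png", dpi=120)
        plt.close(fig)


# ---------------------------------------------------------------------------
# Synthetic input bundle
# ---------------------------------------------------------------------------

def simulate(
    outdir: str | Path,
    seed: int,
    n_hairpins: int = 16,
    days: int = 3,
    depth: int = 2_000_000,
    n_genes: int = 30,
    site_rate: float = 0.3,
    study_like: bool = False,
    truth=None,
) -> RunConfig:
    """Write a complete synthetic input bundle and a ready config.yaml.

    With ``study_like`` the panel is the synthetic study-scale stand-in
    (16 named hairpins with scripted ground truth); otherwise a fresh
    random panel of *n_hairpins* is generated.  Ground truth (panel
    abundances, true repression, planted-site ledger) is written alongside
    the inputs for recovery checks.
    """
    from . import synthetic as syn

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if study_like:
        ds = syn.study_like_panel(seed)
        panel, truth = ds.panel, ds.truth
        true_repression = ds.true_repression
    else:
        panel = syn.gen_panel(n_hairpins, seed)
        truth = truth or syn.SyntheticTruth(rng_seed=seed)
        true_repression = syn.gen_true_repression(panel, truth)

    write_fasta([(m.name, m.sequence) for m in panel.mirnas], outdir / "refs.fasta")
    pairing = pd.DataFrame(
        panel.hairpin_pairs, columns=["hairpin", "name_5p", "name_3p"]
    ).set_index("hairpin")
    write_table(pairing, outdir / "pairing.tsv")

    # blacklist decoy (rRNA-like) plus decoy reads that must be filtered
    rng = np.random.default_rng(seed + 17)
    decoy = "".join(rng.choice(list("ACGU"), size=60))
    write_fasta([("decoy-rRNA", decoy)], outdir / "blacklist.fasta")
    reads_fastas = {}
    for i, rep in enumerate(("rep1", "rep2")):
        counts = syn.gen_read_counts(panel, depth, seed + 100 + i, sampling="poisson")
        collapsed = syn.collapsed_reads(panel, counts)
        collapsed[decoy[10:35]] = 500  # blacklisted; must not be counted
        p = outdir / f"reads_{rep}.fasta"
        write_reads(collapsed, p)
        reads_fastas[rep] = str(p)

    plates = syn.gen_luciferase(true_repression, days, truth, seed + 300)
    write_table(plates.set_index("construct"), outdir / "plates.tsv")

    utr_set = syn.gen_utr_set(panel, n_genes=n_genes, site_rate=site_rate, seed=seed + 400)
    write_fasta([(uid, seq) for _g, uid, seq in utr_set.utrs], outdir / "utrs.fasta")
    write_table(
        utr_set.expression.to_frame().rename_axis("gene"),
        outdir / "mrna_expression.tsv",
    )
    write_table(utr_set.ledger, outdir / "planted_sites.tsv")

    # reporter constructs: insert = exact reverse complement of the mature
    # sequence, flanked by 6 nt of vector context free of panel seed motifs
    motifs = [seed_motif(m.sequence, m.name) for m in panel.mirnas]
    rows = []
    for m in panel.mirnas:
        insert = str(Seq(m.sequence).reverse_complement_rna())
        for _ in range(200):
            up = "".join(rng.choice(list("ACGU"), size=6))
            down = "".join(rng.choice(list("ACGU"), size=6))
            region = up + insert + down
            extra = [
                mo.mirna
                for mo in motifs
                if mo.mirna != m.name and scan_sequence(region, mo)
            ]
            if not extra:
                break
        rows.append(
            {
                "mirna": m.name,
                "mature_sequence": m.sequence,
                "target_with_flanks": up + insert + down,
            }
        )
    write_table(pd.DataFrame(rows).set_index("mirna"), outdir / "constructs.tsv")

    ago = syn.gen_ago_counts(panel, truth, seed + 500)
    ago_reads = {}
    for i, rep in enumerate(("rep1", "rep2")):
        counts = syn.gen_read_counts(
            panel, depth, seed + 600 + i,
            abundance=ago["ago_rpm"].to_dict(), sampling="poisson",
        )
        p = outdir / f"ago_reads_{rep}.fasta"
        write_reads(syn.collapsed_reads(panel, counts), p)
        ago_reads[rep] = str(p)

    truth_frame = pd.DataFrame(
        {
            "true_rpm": panel.rpm_series(),
            "true_repression": pd.Series(true_repression),
            "true_ago_rpm": ago["ago_rpm"],
        }
    ).rename_axis("mirna")
    write_table(truth_frame, outdir / "truth.tsv")

    config = RunConfig(
        refs_fasta=str(outdir / "refs.fasta"),
        pairing_tsv=str(outdir / "pairing.tsv"),
        reads_fastas=reads_fastas,
        plates_tsv=str(outdir / "plates.tsv"),
        utr_fasta=str(outdir / "utrs.fasta"),
        mrna_expression_tsv=str(outdir / "mrna_expression.tsv"),
        constructs_tsv=str(outdir / "constructs.tsv"),
        blacklist_fasta=str(outdir / "blacklist.fasta"),
        ago_reads_fastas=ago_reads,
        outdir=str(outdir / "results"),
        rng_seed=seed,
    )
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    return config
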