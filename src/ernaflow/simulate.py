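"""Synthetic pipeline inputs with planted ground truth.

The generator emulates the statistical structure of a nutlin-3a GRO-seq /
ChIP / ChIRP study on a toy genome: planted enhancer loci covered by
enhancer chromatin states in at least one simulated cell line, carrying p300
and Pol2 peaks, and emitting nascent-read 5' ends on both strands around a
planted midpoint (plus strand downstream, minus strand upstream, exponential
drop-off).  Read counts per region, strand and sample are negative binomial
with the treated-condition mean scaled by the induction fold for induced
loci (divided for repressed ones).  Decoy loci violate exactly one filter
each (unidirectional signal, missing cofactor peak, or no enhancer state).
ChIRP coverage is produced for two probe pools with correlated bump-shaped
coverage at real binding sites — preferentially placed in the designated
strong-enhancer state on induced enhancers — and anti-correlated or
under-sequenced coverage at decoy sites; contaminant sites sit inside a
declared blacklist.

Everything is a deterministic function of ``config.seed``: the same seed
yields byte-identical files from :func:`write_dataset`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .diff import CONTROL, TREATED
from .formats import (
    BedGraphRecord,
    GeneAnnotation,
    PeakCall,
    Transcript,
    write_bed6,
    write_bedgraph,
    write_chromhmm_bed,
    write_gtf,
    write_narrowpeak,
    write_reads_bed6,
)
from .intervals import (
    STRAND_MINUS,
    STRAND_PLUS,
    GenomicInterval,
    SegmentationTrack,
    merge_intervals,
    subtract_intervals,
)
from .methylation import TP53_MUT, TP53_WT, CloneMatrix

BLOCK_BP = 25_000  # private placement grid; one planted feature per block

LABEL_INDUCED = "induced"
LABEL_REPRESSED = "repressed"
LABEL_NEUTRAL = "neutral"

DECOY_UNIDIRECTIONAL = "unidirectional"
DECOY_NO_COFACTOR = "no_cofactor"
DECOY_BAD_STATE = "bad_state"

CHIRP_REAL_STRONG = "real_strong"
CHIRP_REAL_BACKGROUND = "real_background"
CHIRP_ANTICORRELATED = "anticorrelated"
CHIRP_LOW_READS = "low_reads"
CHIRP_CONTAMINANT = "contaminant"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults describe the reference scenario used throughout the test suite:
    a 10-Mb toy genome, ~200 enhancers of which 26% are induced (8-fold) and
    10% repressed so that roughly 72% of the regulated set is induced, three
    replicates per condition with a baseline NB mean of 100 reads per strand
    per sample, and ChIRP binding placed preferentially in the designated
    strong-enhancer state.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length_bp: int = 5_000_000
    n_genes: int = 80
    n_enhancers: int = 200
    n_decoys: int = 45
    frac_induced: float = 0.26
    frac_repressed: float = 0.10
    induction_fold: float = 8.0
    frac_p53_bound: float = 0.5
    nb_dispersion: float = 0.05
    reads_per_enhancer: float = 100.0  # baseline NB mean per strand per sample
    background_reads_per_mb: float = 200.0
    n_replicates: int = 3
    n_cell_lines: int = 3
    enhancer_width_bp: int = 600
    enhancer_state_ids: tuple[int, ...] = (4, 5, 6, 7)
    strong_state_id: int = 4
    n_chirp_sites: int = 40
    chirp_frac_strong_enhancer: float = 0.6
    n_chirp_decoys: int = 8
    contamination_sites: int = 4
    dropoff_scale_bound_bp: float = 250.0
    dropoff_scale_free_bp: float = 600.0

    def __post_init__(self) -> None:
        fracs = {
            "frac_induced": self.frac_induced,
            "frac_repressed": self.frac_repressed,
            "frac_p53_bound": self.frac_p53_bound,
            "chirp_frac_strong_enhancer": self.chirp_frac_strong_enhancer,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_induced + self.frac_repressed > 1.0:
            raise ValueError("frac_induced + frac_repressed must be <= 1")
        positive = {
            "n_chromosomes": self.n_chromosomes,
            "chrom_length_bp": self.chrom_length_bp,
            "n_genes": self.n_genes,
            "n_enhancers": self.n_enhancers,
            "n_replicates": self.n_replicates,
            "n_cell_lines": self.n_cell_lines,
            "enhancer_width_bp": self.enhancer_width_bp,
            "induction_fold": self.induction_fold,
            "reads_per_enhancer": self.reads_per_enhancer,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.strong_state_id not in self.enhancer_state_ids:
            raise ValueError("strong_state_id must be one of enhancer_state_ids")
        n_blocks = self.n_chromosomes * (self.chrom_length_bp // BLOCK_BP)
        n_needed = (
            self.n_genes
            + self.n_enhancers
            + self.n_decoys
            + self.n_chirp_sites
            + self.n_chirp_decoys
            + self.contamination_sites
        )
        if n_needed > n_blocks:
            raise ValueError(
                f"genome too small: {n_needed} features need {n_needed} blocks of "
                f"{BLOCK_BP} bp, only {n_blocks} available"
            )

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length_bp for i in range(self.n_chromosomes)}


@dataclass
class GroundTruth:
    """Planted truth tables (one row per planted feature)."""

    enhancers: pd.DataFrame  # chrom,start,end,midpoint,label,p53_bound,strong_state
    decoys: pd.DataFrame  # chrom,start,end,decoy_type
    chirp_sites: pd.DataFrame  # chrom,start,end,kind,on_induced_enhancer
    genes: pd.DataFrame  # gene_id,induced


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    tracks: list[SegmentationTrack]
    annotations: list[GeneAnnotation]
    p300_peaks: list[PeakCall]
    pol2_peaks: list[PeakCall]
    p53_peaks: list[PeakCall]
    reads: dict[str, pd.DataFrame]  # sample -> frame(chrom, pos, strand)
    conditions: dict[str, str]
    # full-library sizes (sequencing depth); on this toy genome the planted
    # loci dominate the emitted reads, so per-file totals would carry a
    # composition artifact a real library would not have
    library_sizes: dict[str, float]
    chirp_odd_peaks: list[PeakCall]
    chirp_even_peaks: list[PeakCall]
    chirp_odd_cov: list[BedGraphRecord]
    chirp_even_cov: list[BedGraphRecord]
    contaminant_blacklist: list[GenomicInterval]
    truth: GroundTruth

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return self.config.chrom_lengths

    def reads_as_records(self, sample: str):
        from .formats import Read5p

        df = self.reads[sample]
        return [Read5p(c, int(p), s) for c, p, s in df.itertuples(index=False)]

    def read_index(self, samples: Sequence[str] | None = None):
        """A :class:`~ernaflow.discovery.ReadIndex` over the given samples
        (default: all)."""
        from .discovery import ReadIndex

        wanted = list(self.reads) if samples is None else list(samples)
        frames = [self.reads[s] for s in wanted]
        df = pd.concat(frames, ignore_index=True)
        idx = ReadIndex([])
        for (chrom, strand), sub in df.groupby(["chrom", "strand"], sort=True):
            idx._arr[(chrom, strand)] = np.sort(sub["pos"].to_numpy(dtype=np.int64))
            idx.n_reads += len(sub)
        return idx


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _assign_blocks(config: SimulationConfig, rng: np.random.Generator):
    blocks = [
        (f"chr{c + 1}", b * BLOCK_BP)
        for c in range(config.n_chromosomes)
        for b in range(config.chrom_length_bp // BLOCK_BP)
    ]
    order = rng.permutation(len(blocks))
    it = iter(order)

    def take(n: int) -> list[tuple[str, int]]:
        return [blocks[next(it)] for _ in range(n)]

    return {
        "genes": take(config.n_genes),
        "enhancers": take(config.n_enhancers),
        "decoys": take(config.n_decoys),
        "chirp": take(config.n_chirp_sites),
        "chirp_decoys": take(config.n_chirp_decoys),
        "contaminants": take(config.contamination_sites),
    }


def _make_genes(
    config: SimulationConfig, rng: np.random.Generator, blocks: list[tuple[str, int]]
) -> tuple[list[GeneAnnotation], pd.DataFrame]:
    genes: list[GeneAnnotation] = []
    rows = []
    for i, (chrom, bstart) in enumerate(blocks):
        length = int(rng.integers(3_000, 8_001))
        start = bstart + 2_000
        strand = STRAND_PLUS if rng.random() < 0.5 else STRAND_MINUS
        gid = f"gene_{i}"
        span = GenomicInterval(chrom, start, start + length, strand)
        exon1 = GenomicInterval(chrom, start, start + 400, strand)
        exon2 = GenomicInterval(chrom, start + length - 400, start + length, strand)
        txs = [Transcript(f"{gid}.t1", span, (exon1, exon2))]
        if rng.random() < 0.2:  # same-strand overlapping isoform
            span2 = GenomicInterval(chrom, start + 1_000, start + length + 500, strand)
            txs.append(
                Transcript(
                    f"{gid}.t2",
                    span2,
                    (GenomicInterval(chrom, start + 1_000, start + 1_400, strand),
                     GenomicInterval(chrom, start + length, start + length + 500, strand)),
                )
            )
        genes.append(GeneAnnotation(gid, tuple(txs)))
        rows.append({"gene_id": gid, "induced": bool(rng.random() < 0.3)})
    return genes, pd.DataFrame(rows)


def _nb_counts(
    rng: np.random.Generator, mean: float, dispersion: float, size: int
) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    if dispersion == 0.0:
        return rng.poisson(mean, size=size).astype(np.int64)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean), size=size).astype(np.int64)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate every pipeline input plus the planted ground truth."""
    rng = np.random.default_rng(config.seed)
    blocks = _assign_blocks(config, rng)
    chrom_lengths = config.chrom_lengths

    annotations, gene_truth = _make_genes(config, rng, blocks["genes"])

    # --- enhancers -------------------------------------------------------
    half = config.enhancer_width_bp // 2
    enh_rows = []
    for i, (chrom, bstart) in enumerate(blocks["enhancers"]):
        mid = bstart + BLOCK_BP // 2 + int(rng.integers(-2_000, 2_001))
        u = rng.random()
        if u < config.frac_induced:
            label = LABEL_INDUCED
        elif u < config.frac_induced + config.frac_repressed:
            label = LABEL_REPRESSED
        else:
            label = LABEL_NEUTRAL
        bound = label == LABEL_INDUCED and rng.random() < config.frac_p53_bound
        strong = bool(rng.random() < 0.5)
        enh_rows.append(
            {
                "enh_id": f"enh_{i}",
                "chrom": chrom,
                "start": mid - half,
                "end": mid + half,
                "midpoint": mid,
                "label": label,
                "p53_bound": bound,
                "strong_state": strong,
            }
        )
    enh = pd.DataFrame(enh_rows)

    decoy_types = [DECOY_UNIDIRECTIONAL, DECOY_NO_COFACTOR, DECOY_BAD_STATE]
    decoy_rows = []
    for i, (chrom, bstart) in enumerate(blocks["decoys"]):
        mid = bstart + BLOCK_BP // 2
        decoy_rows.append(
            {
                "decoy_id": f"decoy_{i}",
                "chrom": chrom,
                "start": mid - half,
                "end": mid + half,
                "midpoint": mid,
                "decoy_type": decoy_types[i % len(decoy_types)],
            }
        )
    decoys = pd.DataFrame(decoy_rows)

    # --- segmentation tracks --------------------------------------------
    generic_states = [s for s in config.enhancer_state_ids if s != config.strong_state_id]
    tracks: list[SegmentationTrack] = []
    enh_state = [
        config.strong_state_id
        if row.strong_state
        else generic_states[i % len(generic_states)] if generic_states else config.strong_state_id
        for i, row in enumerate(enh.itertuples())
    ]
    covered_by = [
        [line for line in range(config.n_cell_lines) if rng.random() < 0.7]
        or [int(rng.integers(config.n_cell_lines))]
        for _ in range(len(enh))
    ]
    for line in range(config.n_cell_lines):
        segs: list[tuple[GenomicInterval, int]] = []
        for i, row in enumerate(enh.itertuples()):
            if line in covered_by[i]:
                iv = GenomicInterval(row.chrom, row.start - 200, row.end + 200)
                segs.append((iv, enh_state[i]))
        if line == 0:  # decoys that need a state: only on the first line
            for row in decoys.itertuples():
                if row.decoy_type != DECOY_BAD_STATE:
                    iv = GenomicInterval(row.chrom, row.start - 200, row.end + 200)
                    segs.append((iv, config.enhancer_state_ids[-1]))
        enhancer_ivs = [iv for iv, _s in segs]
        background = subtract_intervals(
            [GenomicInterval(c, 0, ln) for c, ln in chrom_lengths.items()],
            merge_intervals(enhancer_ivs),
        )
        segs.extend((iv, 1) for iv in background)
        tracks.append(SegmentationTrack(cell_line=f"cell_{line}", segments=segs))

    # --- ChIP peaks ------------------------------------------------------
    p300: list[PeakCall] = []
    pol2: list[PeakCall] = []
    p53: list[PeakCall] = []

    def cofactor(chrom: str, mid: int, name: str) -> PeakCall:
        return PeakCall(
            interval=GenomicInterval(chrom, mid - 150, mid + 150),
            fold_enrichment=float(rng.uniform(4, 10)),
            neg_log10_q=float(rng.uniform(5, 30)),
            summit_offset=150,
            name=name,
        )

    for i, row in enumerate(enh.itertuples()):
        p300.append(cofactor(row.chrom, row.midpoint, f"p300_enh_{i}"))
        pol2.append(cofactor(row.chrom, row.midpoint, f"pol2_enh_{i}"))
        if row.p53_bound:
            gap = int(rng.integers(0, 701))  # edge gap 0-700 bp <= 1-kb rule
            if rng.random() < 0.5:  # overlap instead of gap
                start = row.midpoint - 150
            else:
                start = row.end + gap
            p53.append(
                PeakCall(
                    interval=GenomicInterval(row.chrom, start, start + 300),
                    fold_enrichment=float(rng.uniform(3.5, 12)),
                    neg_log10_q=float(rng.uniform(2.5, 20)),
                    summit_offset=150,
                    name=f"p53_enh_{i}",
                )
            )
        elif row.label == LABEL_INDUCED and rng.random() < 0.3:
            # sub-threshold p53 peak: must be discarded by the peak filter
            start = row.end + int(rng.integers(0, 501))
            p53.append(
                PeakCall(
                    interval=GenomicInterval(row.chrom, start, start + 300),
                    fold_enrichment=float(rng.uniform(0.5, 2.9)),
                    neg_log10_q=float(rng.uniform(0.0, 1.9)),
                    name=f"p53_weak_enh_{i}",
                )
            )
    for i, row in enumerate(decoys.itertuples()):
        if row.decoy_type == DECOY_NO_COFACTOR:
            p300.append(cofactor(row.chrom, row.midpoint, f"p300_decoy_{i}"))
        else:
            p300.append(cofactor(row.chrom, row.midpoint, f"p300_decoy_{i}"))
            pol2.append(cofactor(row.chrom, row.midpoint, f"pol2_decoy_{i}"))

    # --- nascent reads ---------------------------------------------------
    samples = [f"ctrl_{r + 1}" for r in range(config.n_replicates)] + [
        f"trt_{r + 1}" for r in range(config.n_replicates)
    ]
    conditions = {
        s: (CONTROL if s.startswith("ctrl") else TREATED) for s in samples
    }
    depth = {s: float(rng.uniform(0.85, 1.15)) for s in samples}

    def emit(chrom: str, mid: int, n_plus: int, n_minus: int, scale: float, store):
        length = chrom_lengths[chrom]
        if n_plus:
            d = np.floor(rng.exponential(scale, size=n_plus)).astype(np.int64)
            pos = np.clip(mid + d, 0, length - 1)
            store.append((chrom, pos, STRAND_PLUS))
        if n_minus:
            d = np.floor(rng.exponential(scale, size=n_minus)).astype(np.int64)
            pos = np.clip(mid - 1 - d, 0, length - 1)
            store.append((chrom, pos, STRAND_MINUS))

    reads: dict[str, pd.DataFrame] = {}
    for s in samples:
        store: list[tuple[str, np.ndarray, str]] = []
        treated = conditions[s] == TREATED
        for i, row in enumerate(enh.itertuples()):
            mu = config.reads_per_enhancer * depth[s]
            if treated and row.label == LABEL_INDUCED:
                mu *= config.induction_fold
            elif treated and row.label == LABEL_REPRESSED:
                mu /= config.induction_fold
            scale = (
                config.dropoff_scale_bound_bp
                if row.p53_bound
                else config.dropoff_scale_free_bp
            )
            n_plus, n_minus = _nb_counts(rng, mu, config.nb_dispersion, 2)
            emit(row.chrom, row.midpoint, int(n_plus), int(n_minus), scale, store)
        for row in decoys.itertuples():
            mu = config.reads_per_enhancer * depth[s]
            n_plus, n_minus = _nb_counts(rng, mu, config.nb_dispersion, 2)
            if row.decoy_type == DECOY_UNIDIRECTIONAL:
                n_minus = 0
            emit(row.chrom, row.midpoint, int(n_plus), int(n_minus),
                 config.dropoff_scale_free_bp, store)
        total_mb = sum(chrom_lengths.values()) / 1e6
        n_bg = int(rng.poisson(config.background_reads_per_mb * total_mb * depth[s]))
        chrom_names = sorted(chrom_lengths)
        bg_chrom = rng.integers(0, len(chrom_names), size=n_bg)
        bg_strand = rng.random(n_bg) < 0.5
        for ci, chrom in enumerate(chrom_names):
            for strand, mask_s in ((STRAND_PLUS, bg_strand), (STRAND_MINUS, ~bg_strand)):
                mask = (bg_chrom == ci) & mask_s
                n = int(mask.sum())
                if n:
                    pos = rng.integers(0, chrom_lengths[chrom], size=n)
                    store.append((chrom, pos.astype(np.int64), strand))
        frames = [
            pd.DataFrame({"chrom": chrom, "pos": pos, "strand": strand})
            for chrom, pos, strand in store
        ]
        df = pd.concat(frames, ignore_index=True)
        reads[s] = df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(
            drop=True
        )

    # --- ChIRP -----------------------------------------------------------
    chirp = _simulate_chirp(config, rng, enh, blocks)

    truth = GroundTruth(
        enhancers=enh,
        decoys=decoys,
        chirp_sites=chirp["sites"],
        genes=gene_truth,
    )
    return SimulatedDataset(
        config=config,
        tracks=tracks,
        annotations=annotations,
        p300_peaks=p300,
        pol2_peaks=pol2,
        p53_peaks=p53,
        reads=reads,
        conditions=conditions,
        library_sizes={s: depth[s] * 1e6 for s in samples},
        chirp_odd_peaks=chirp["odd_peaks"],
        chirp_even_peaks=chirp["even_peaks"],
        chirp_odd_cov=chirp["odd_cov"],
        chirp_even_cov=chirp["even_cov"],
        contaminant_blacklist=chirp["blacklist"],
        truth=truth,
    )


def _bump_coverage(
    chrom: str,
    start: int,
    end: int,
    reads: float,
    rng: np.random.Generator,
    step: int = 20,
    shape: str = "bump",
) -> list[BedGraphRecord]:
    """Piecewise-constant coverage over [start, end) summing to ``reads``.

    "bump" is a noisy triangular profile (correlated across pools when drawn
    twice from the same span), "ramp_up"/"ramp_down" are monotone profiles
    used to build anti-correlated decoy pairs.
    """
    edges = np.arange(start, end, step)
    widths = np.minimum(edges + step, end) - edges
    centers = edges + widths / 2.0
    c = (start + end) / 2.0
    if shape == "bump":
        base = 1.0 - np.abs(centers - c) / ((end - start) / 2.0)
        base *= rng.uniform(0.9, 1.1, size=len(base))
    elif shape == "ramp_up":
        base = (centers - start) / (end - start)
    elif shape == "ramp_down":
        base = (end - centers) / (end - start)
    else:  # pragma: no cover
        raise ValueError(shape)
    base = np.clip(base, 1e-3, None)
    per_base_mass = base / float(np.sum(base * widths))
    values = per_base_mass * reads
    return [
        BedGraphRecord(chrom, int(e), int(e + w), float(v))
        for e, w, v in zip(edges, widths, values)
    ]


def _simulate_chirp(
    config: SimulationConfig,
    rng: np.random.Generator,
    enh: pd.DataFrame,
    blocks: dict[str, list[tuple[str, int]]],
):
    site_rows = []
    n_strong = int(round(config.n_chirp_sites * config.chirp_frac_strong_enhancer))
    strong_mask = enh["strong_state"].to_numpy()
    induced_mask = (enh["label"] == LABEL_INDUCED).to_numpy()
    strong_induced = np.flatnonzero(strong_mask & induced_mask)
    strong_other = np.flatnonzero(strong_mask & ~induced_mask)
    # binding prefers induced enhancers (3:1) so the induced-in-bound
    # hypergeometric enrichment is planted
    picks: list[int] = []
    n_from_induced = min(len(strong_induced), int(round(n_strong * 0.75)))
    picks.extend(rng.choice(strong_induced, size=n_from_induced, replace=False))
    rest = n_strong - n_from_induced
    if rest > 0:
        rest = min(rest, len(strong_other))
        picks.extend(rng.choice(strong_other, size=rest, replace=False))
    for idx in picks:
        row = enh.iloc[int(idx)]
        site_rows.append(
            {
                "chrom": row["chrom"],
                "start": int(row["midpoint"]) - 200,
                "end": int(row["midpoint"]) + 200,
                "kind": CHIRP_REAL_STRONG,
                "on_induced_enhancer": bool(row["label"] == LABEL_INDUCED),
                "enh_id": row["enh_id"],
            }
        )
    n_background = config.n_chirp_sites - len(picks)
    for chrom, bstart in blocks["chirp"][:n_background]:
        mid = bstart + BLOCK_BP // 2
        site_rows.append(
            {
                "chrom": chrom,
                "start": mid - 200,
                "end": mid + 200,
                "kind": CHIRP_REAL_BACKGROUND,
                "on_induced_enhancer": False,
                "enh_id": "",
            }
        )
    for i, (chrom, bstart) in enumerate(blocks["chirp_decoys"]):
        mid = bstart + BLOCK_BP // 2
        site_rows.append(
            {
                "chrom": chrom,
                "start": mid - 200,
                "end": mid + 200,
                "kind": CHIRP_ANTICORRELATED if i % 2 == 0 else CHIRP_LOW_READS,
                "on_induced_enhancer": False,
                "enh_id": "",
            }
        )
    blacklist = []
    for chrom, bstart in blocks["contaminants"]:
        mid = bstart + BLOCK_BP // 2
        blacklist.append(GenomicInterval(chrom, mid - 500, mid + 500))
        site_rows.append(
            {
                "chrom": chrom,
                "start": mid - 200,
                "end": mid + 200,
                "kind": CHIRP_CONTAMINANT,
                "on_induced_enhancer": False,
                "enh_id": "",
            }
        )
    sites = pd.DataFrame(site_rows)

    odd_peaks: list[PeakCall] = []
    even_peaks: list[PeakCall] = []
    odd_cov: list[BedGraphRecord] = []
    even_cov: list[BedGraphRecord] = []

    def peak(chrom: str, start: int, end: int, name: str, strong: bool, pool: str) -> PeakCall:
        return PeakCall(
            interval=GenomicInterval(chrom, start, end),
            fold_enrichment=float(rng.uniform(4.0, 15.0)) if strong else float(rng.uniform(0.5, 3.9)),
            neg_log10_q=float(rng.uniform(5.0, 40.0)) if strong else float(rng.uniform(0.0, 4.9)),
            name=name,
            pool=pool,
        )

    for i, row in enumerate(sites.itertuples()):
        chrom, start, end = row.chrom, int(row.start), int(row.end)
        if row.kind == CHIRP_ANTICORRELATED:
            reads_odd = reads_even = float(rng.uniform(40, 80))
            odd_cov.extend(_bump_coverage(chrom, start, end, reads_odd, rng, shape="ramp_up"))
            even_cov.extend(_bump_coverage(chrom, start, end, reads_even, rng, shape="ramp_down"))
        elif row.kind == CHIRP_LOW_READS:
            odd_cov.extend(_bump_coverage(chrom, start, end, 10.0, rng))
            even_cov.extend(_bump_coverage(chrom, start, end, 10.0, rng))
        else:
            odd_cov.extend(_bump_coverage(chrom, start, end, float(rng.uniform(40, 80)), rng))
            even_cov.extend(_bump_coverage(chrom, start, end, float(rng.uniform(40, 80)), rng))
        jitter = int(rng.integers(-30, 31))
        odd_peaks.append(peak(chrom, start + jitter, end + jitter, f"odd_{i}", True, "odd"))
        even_peaks.append(peak(chrom, start - jitter, end - jitter, f"even_{i}", True, "even"))

    # sub-threshold pool peaks over flat coverage: removed by the q/enr filter
    for j, (chrom, bstart) in enumerate(blocks["chirp"][n_background : n_background + 3]):
        mid = bstart + BLOCK_BP // 2 + 5_000
        odd_peaks.append(peak(chrom, mid - 200, mid + 200, f"odd_weak_{j}", False, "odd"))
        even_peaks.append(peak(chrom, mid - 200, mid + 200, f"even_weak_{j}", False, "even"))

    def sort_cov(records: list[BedGraphRecord]) -> list[BedGraphRecord]:
        return sorted(records, key=lambda r: (r.chrom, r.start))

    return {
        "sites": sites,
        "odd_peaks": odd_peaks,
        "even_peaks": even_peaks,
        "odd_cov": sort_cov(odd_cov),
        "even_cov": sort_cov(even_cov),
        "blacklist": blacklist,
    }


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Write the dataset as the standard on-disk formats plus truth TSVs.

    Layout: ``segmentations/<cell>.bed``, ``annotations.gtf``,
    ``peaks/{p300,pol2,p53}.narrowPeak``, ``reads/<sample>.bed``,
    ``chirp/{odd,even}.{narrowPeak,bedGraph}``, ``chirp/contaminants.bed``,
    ``conditions.tsv`` and ``truth/*.tsv``.  Output is byte-identical for a
    given config (ordering is fully deterministic).
    """
    out = Path(outdir)
    for sub in ("segmentations", "peaks", "reads", "chirp", "truth"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    for track in dataset.tracks:
        write_chromhmm_bed(out / "segmentations" / f"{track.cell_line}.bed", track)
    write_gtf(out / "annotations.gtf", dataset.annotations)
    write_narrowpeak(out / "peaks" / "p300.narrowPeak", dataset.p300_peaks)
    write_narrowpeak(out / "peaks" / "pol2.narrowPeak", dataset.pol2_peaks)
    write_narrowpeak(out / "peaks" / "p53.narrowPeak", dataset.p53_peaks)
    for sample in sorted(dataset.reads):
        write_reads_bed6(out / "reads" / f"{sample}.bed",
                         dataset.reads_as_records(sample))
    write_narrowpeak(out / "chirp" / "odd.narrowPeak", dataset.chirp_odd_peaks)
    write_narrowpeak(out / "chirp" / "even.narrowPeak", dataset.chirp_even_peaks)
    write_bedgraph(out / "chirp" / "odd.bedGraph", dataset.chirp_odd_cov)
    write_bedgraph(out / "chirp" / "even.bedGraph", dataset.chirp_even_cov)
    write_bed6(out / "chirp" / "contaminants.bed", dataset.contaminant_blacklist)

    with open(out / "conditions.tsv", "w") as fh:
        fh.write("sample\tcondition\tlibrary_size\n")
        for s in sorted(dataset.conditions):
            fh.write(
                f"{s}\t{dataset.conditions[s]}\t{dataset.library_sizes[s]:.1f}\n"
            )

    dataset.truth.enhancers.to_csv(out / "truth" / "enhancers.tsv", sep="\t", index=False)
    dataset.truth.decoys.to_csv(out / "truth" / "decoys.tsv", sep="\t", index=False)
    dataset.truth.chirp_sites.to_csv(out / "truth" / "chirp_sites.tsv", sep="\t", index=False)
    dataset.truth.genes.to_csv(out / "truth" / "genes.tsv", sep="\t", index=False)
    with open(out / "config.yaml", "w") as fh:
        import yaml

        yaml.safe_dump(dataclasses.asdict(dataset.config), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# methylation cohort
# ---------------------------------------------------------------------------


def simulate_methylation_cohort(
    n_wt: int = 48,
    n_mut: int = 87,
    p_meth_wt: float = 0.60,
    p_meth_mut: float = 0.34,
    clones_per_sample: int = 10,
    n_cpgs: int = 20,
    seed: int = 0,
    tumour_types: Sequence[str] | None = None,
    missing_rate: float = 0.02,
) -> list[CloneMatrix]:
    """Bisulfite-clone cohort with TP53-status-dependent methylation.

    Each sample is hypermethylated with its group's probability; clone
    entries are then Bernoulli draws around the sample-level propensity
    (0.85 methylated-state, 0.08 unmethylated-state) with a small missing
    rate.  Ten clones per sample is the default display convention.
    """
    for p in (p_meth_wt, p_meth_mut, missing_rate):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must be in [0, 1]")
    if clones_per_sample < 1 or n_cpgs < 1:
        raise ValueError("clones_per_sample and n_cpgs must be >= 1")
    rng = np.random.default_rng(seed)
    cohort: list[CloneMatrix] = []
    specs = [(TP53_WT, n_wt, p_meth_wt), (TP53_MUT, n_mut, p_meth_mut)]
    i = 0
    for status, n, p_group in specs:
        for _ in range(n):
            hyper = rng.random() < p_group
            p_cpg = 0.85 if hyper else 0.08
            m = (rng.random((clones_per_sample, n_cpgs)) < p_cpg).astype(float)
            miss = rng.random((clones_per_sample, n_cpgs)) < missing_rate
            m[miss] = np.nan
            ttype = (
                tumour_types[i % len(tumour_types)] if tumour_types else None
            )
            cohort.append(
                CloneMatrix(
                    sample_id=f"sample_{i}",
                    tp53_status=status,
                    matrix=m,
                    tumour_type=ttype,
                )
            )
            i += 1
    return cohort
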