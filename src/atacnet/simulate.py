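"""Synthetic two-condition ATAC-seq datasets with known ground truth.

Emulates the structure of an isogenic two-condition chromatin-accessibility
study run in biological duplicate: a uniform-composition genome, gene
models, shared and condition-unique peaks, negative-binomial fragment
counts, TF motif instances implanted into condition-A-unique peaks, an
expression table whose upregulated genes host condition-A peaks, and an
H3K27ac / super-enhancer layer covering part of the condition-A peaks.

Every quantity the downstream pipeline is supposed to recover is recorded
in truth tables, so recovery can be scored exactly.  All randomness flows
from one integer seed through named `numpy.random.SeedSequence` children
(one per generation stage), so stages are independently reproducible and
identical seeds give byte-identical output files.

What this generator does NOT emulate: read-level data (counts are drawn
per peak), sequence-composition structure (CpG islands, repeats), and any
coupling between condition B and expression (the emulated contrast is
one-sided: the "tumor" condition A gains accessibility at upregulated
genes, mirroring a parental-versus-edited design).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel, write_gene_models_bed12
from .differential import CountMatrix, Sample
from .expression import ExpressionRecord, write_expression_table
from .intervals import GenomicInterval, IntervalSet, intersect, merge, write_bed
from .motifs import PWM, fixture_library, reverse_complement

logger = logging.getLogger(__name__)

BASES = "ACGT"

# placement geometry (bp)
PEAK_MARGIN = 100          # minimum gap between any two peaks
UNIQUE_A_MARGIN = 3600     # gap between condition-A-unique peaks, so their
                           # +-500 bp H3K27ac pads never chain into spurious
                           # super-enhancer clusters (merge gap 1000)
H3K27AC_PAD = 500
SE_MERGE_GAP = 1000
SE_FLANK_GAP = 800
SE_FLANK_WIDTH = 600


class PlacementError(RuntimeError):
    """Raised when features cannot be placed at the requested density."""


@dataclass
class SimulationConfig:
    """Generator parameters.

    The negative-binomial parameterization is (mean, dispersion) with
    variance = mean + dispersion * mean**2.  ``implant_rate`` is the
    fraction of condition-A-unique peaks receiving a motif instance;
    ``coupled_fraction`` is the fraction of condition-A-unique peaks placed
    inside the body of a gene that the expression table will call
    upregulated.
    """

    n_chromosomes: int = 2
    chrom_length: int = 900_000
    n_genes: int = 150
    n_shared_peaks: int = 150
    n_unique_peaks_per_condition: int = 50
    peak_width_range: tuple[int, int] = (200, 400)
    replicates_per_condition: int = 2
    nb_mean: float = 100.0
    nb_dispersion: float = 0.1
    closed_count_mean: float = 5.0
    implant_rate: float = 0.5
    coupled_fraction: float = 0.6
    lfc_mean: float = 2.0
    lfc_sd: float = 0.5
    h3k27ac_coverage: float = 0.8
    n_super_enhancers: int = 10
    gene_length_range: tuple[int, int] = (2000, 5000)
    min_gene_spacing: int = 6000
    boundary_jitter: int = 20
    condition_a: str = "K27M"
    condition_b: str = "WT"
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_chromosomes, self.chrom_length, self.n_genes, self.n_shared_peaks,
            self.n_unique_peaks_per_condition, self.replicates_per_condition,
            self.n_super_enhancers, self.boundary_jitter,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ValueError("need at least one chromosome of positive length")
        for lo, hi in (self.peak_width_range, self.gene_length_range):
            if lo <= 0 or hi < lo:
                raise ValueError("width ranges must be positive and ordered")
        for rate in (self.implant_rate, self.coupled_fraction, self.h3k27ac_coverage):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if min(self.nb_mean, self.closed_count_mean) <= 0 or self.nb_dispersion < 0:
            raise ValueError("count-model parameters must be positive (dispersion >= 0)")
        if self.lfc_sd <= 0:
            raise ValueError("lfc_sd must be positive")
        if self.replicates_per_condition < 2:
            logger.warning(
                "replicates_per_condition < 2: occupancy-based unique-peak "
                "calling assumes duplicates"
            )
        self._check_capacity()

    def _check_capacity(self) -> None:
        if self.n_genes > 0:
            per_chrom = -(-self.n_genes // self.n_chromosomes)  # ceil
            slot = self.chrom_length // per_chrom
            need = self.gene_length_range[1] + self.min_gene_spacing
            if slot < need:
                raise PlacementError(
                    f"cannot place {self.n_genes} genes of up to "
                    f"{self.gene_length_range[1]} bp with {self.min_gene_spacing} bp "
                    f"spacing on {self.n_chromosomes} x {self.chrom_length} bp "
                    f"chromosomes (slot {slot} < required {need})"
                )
        n_peaks = self.n_shared_peaks + 2 * self.n_unique_peaks_per_condition
        peak_footprint = (
            n_peaks * (self.peak_width_range[1] + PEAK_MARGIN)
            + self.n_unique_peaks_per_condition * UNIQUE_A_MARGIN
        )
        genome = self.n_chromosomes * self.chrom_length
        if peak_footprint > 0.5 * genome:
            raise PlacementError(
                f"peak footprint ~{peak_footprint} bp exceeds half the "
                f"{genome} bp genome; reduce peak number/width or enlarge genome"
            )

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def sample_layout(self) -> list[Sample]:
        out = []
        for cond in (self.condition_a, self.condition_b):
            for r in range(1, self.replicates_per_condition + 1):
                out.append(Sample(f"{cond}_rep{r}", cond, r))
        return out


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    flagged_genes: set[str]
    samples: list[Sample]
    sample_peaks: dict[str, IntervalSet]
    counts: CountMatrix
    expression: list[ExpressionRecord]
    h3k27ac: IntervalSet
    super_enhancers: IntervalSet
    truth_peaks: pd.DataFrame
    truth_se: pd.DataFrame

    def true_peaks(self, condition: str | None = None) -> IntervalSet:
        """Truth peak intervals, optionally restricted to one uniqueness class.

        ``condition`` may be a condition name (that condition's unique
        peaks), "shared", or None for all true peaks.
        """
        df = self.truth_peaks
        if condition is not None:
            df = df[df["condition"] == condition]
        return IntervalSet(
            [
                GenomicInterval(r.chrom, int(r.start), int(r.end), name=r.peak_id)
                for r in df.itertuples()
            ],
            label=condition or "true_peaks",
        )


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Named per-stage generators from one root seed (fixed spawn order)."""
    names = ["genome", "genes", "peaks", "jitter", "counts", "implant",
             "expression", "h3k27ac"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def generate_genome(
    config: SimulationConfig,
    rng_genome: np.random.Generator | None = None,
    rng_genes: np.random.Generator | None = None,
) -> tuple[dict[str, str], list[GeneModel]]:
    """I.i.d. uniform-composition chromosomes plus non-overlapping gene models.

    Genes are laid out in equal slots per chromosome with at least
    ``min_gene_spacing`` bp between neighbors (so regulatory domains built
    later cover each gene's own body), random strand, and 2-4 exons whose
    first/last blocks touch the body ends.
    """
    if rng_genome is None or rng_genes is None:
        rngs = _stage_rngs(config.seed)
        rng_genome = rngs["genome"]
        rng_genes = rngs["genes"]
    genome = {
        name: "".join(np.array(list(BASES))[rng_genome.integers(0, 4, config.chrom_length)])
        for name in config.chrom_names()
    }
    genes: list[GeneModel] = []
    if config.n_genes:
        per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
        per_chrom[: config.n_genes % config.n_chromosomes] += 1
        margin = config.min_gene_spacing // 2
        idx = 0
        for chrom, n_on in zip(config.chrom_names(), per_chrom):
            if n_on == 0:
                continue
            slot = config.chrom_length // int(n_on)
            for j in range(int(n_on)):
                length = int(rng_genes.integers(*config.gene_length_range, endpoint=True))
                lo = j * slot + margin
                hi = (j + 1) * slot - margin - length
                if hi < lo:
                    raise PlacementError(
                        f"gene slot on {chrom} too small for a {length} bp gene"
                    )
                start = int(rng_genes.integers(lo, hi + 1))
                strand = "+" if rng_genes.random() < 0.5 else "-"
                body = GenomicInterval(chrom, start, start + length)
                n_exons = int(rng_genes.integers(2, 5))
                cuts = np.sort(
                    rng_genes.choice(np.arange(1, length), size=2 * n_exons - 2, replace=False)
                )
                bounds = np.concatenate([[0], cuts, [length]])
                exons = tuple(
                    GenomicInterval(chrom, start + int(bounds[2 * e]), start + int(bounds[2 * e + 1]))
                    for e in range(n_exons)
                )
                gene_id = f"gene_{idx:04d}"
                idx += 1
                genes.append(
                    GeneModel(
                        gene_id,
                        chrom,
                        strand,
                        GenomicInterval(chrom, start, start + length, name=gene_id, strand=strand),
                        tuple(
                            GenomicInterval(e.chrom, e.start, e.end, name=gene_id, strand=strand)
                            for e in exons
                        ),
                    )
                )
    return genome, genes


def _choose_flagged_genes(genes: list[GeneModel], n: int, rng: np.random.Generator) -> list[GeneModel]:
    """Sample n genes no two of which are genomic neighbors.

    Non-adjacency keeps every synthetic super-enhancer attributable to a
    single upregulated gene (adjacent regulatory domains abut).
    """
    order = sorted(genes, key=lambda g: (g.chrom, g.body.start))
    pos = {g.gene_id: i for i, g in enumerate(order)}
    chosen: list[GeneModel] = []
    taken: set[int] = set()
    for i in rng.permutation(len(order)):
        i = int(i)
        if i in taken or (i - 1) in taken or (i + 1) in taken:
            continue
        chosen.append(order[i])
        taken.add(i)
        if len(chosen) == n:
            return chosen
    raise PlacementError(
        f"cannot choose {n} pairwise non-adjacent genes out of {len(genes)}"
    )


class _PeakPlacer:
    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.placed: list[tuple[str, int, int, bool]] = []  # chrom, start, end, is_unique_a
        self.forbidden: list[tuple[str, int, int]] = []

    def forbid(self, chrom: str, start: int, end: int) -> None:
        self.forbidden.append((chrom, start, end))

    def _conflicts(self, chrom: str, start: int, end: int, is_unique_a: bool) -> bool:
        for c, s, e, ua in self.placed:
            if c != chrom:
                continue
            gap = UNIQUE_A_MARGIN if (is_unique_a and ua) else PEAK_MARGIN
            if start < e + gap and s < end + gap:
                return True
        for c, s, e in self.forbidden:
            if c == chrom and start < e and s < end:
                return True
        return False

    def place_inside(self, chrom: str, lo: int, hi: int, is_unique_a: bool) -> GenomicInterval:
        """Place one peak within [lo, hi); used for gene-body-coupled peaks."""
        for _ in range(1000):
            width = int(self.rng.integers(*self.config.peak_width_range, endpoint=True))
            if hi - lo < width:
                break
            start = int(self.rng.integers(lo, hi - width + 1))
            if not self._conflicts(chrom, start, start + width, is_unique_a):
                self.placed.append((chrom, start, start + width, is_unique_a))
                return GenomicInterval(chrom, start, start + width)
        raise PlacementError(f"cannot place a peak inside {chrom}:{lo}-{hi}")

    def place_anywhere(self, is_unique_a: bool) -> GenomicInterval:
        cfg = self.config
        chroms = cfg.chrom_names()
        for _ in range(5000):
            chrom = chroms[int(self.rng.integers(0, len(chroms)))]
            width = int(self.rng.integers(*cfg.peak_width_range, endpoint=True))
            start = int(self.rng.integers(0, cfg.chrom_length - width))
            if not self._conflicts(chrom, start, start + width, is_unique_a):
                self.placed.append((chrom, start, start + width, is_unique_a))
                return GenomicInterval(chrom, start, start + width)
        raise PlacementError(
            "peak placement failed after 5000 attempts: genome too dense "
            f"({len(self.placed)} peaks placed)"
        )


def generate_peaks_and_counts(
    genome: Mapping[str, str],
    genes: list[GeneModel],
    config: SimulationConfig,
    rng_peaks: np.random.Generator,
    rng_jitter: np.random.Generator,
    rng_counts: np.random.Generator,
) -> tuple[list[GeneModel], dict[str, IntervalSet], CountMatrix, pd.DataFrame]:
    """Place true peaks, build per-sample peak sets and the count matrix.

    Returns (flagged genes, per-sample peak sets, counts, truth table).
    Condition-A-unique peaks are coupled to upregulated-gene bodies at
    ``coupled_fraction``; remaining peaks avoid flagged gene bodies so the
    coupling truth stays exact.  Per-sample peak boundaries are jittered by
    up to ``boundary_jitter`` bp to mimic replicate-to-replicate peak-call
    variation without breaking presence/absence structure.
    """
    n_unique = config.n_unique_peaks_per_condition
    n_coupled = round(config.coupled_fraction * n_unique)
    flagged = _choose_flagged_genes(genes, n_coupled, rng_peaks) if n_coupled else []
    placer = _PeakPlacer(config, rng_peaks)
    for g in flagged:
        placer.forbid(g.chrom, g.body.start, g.body.end)
    # coupled peaks go inside flagged gene bodies (forbidden list guards the
    # other placements, so couple first via place_inside which ignores it)
    placer.forbidden, saved = [], placer.forbidden
    records = []
    for g in flagged:
        iv = placer.place_inside(g.chrom, g.body.start, g.body.end, is_unique_a=True)
        records.append((iv, config.condition_a, g.gene_id))
    placer.forbidden = saved
    for _ in range(n_unique - n_coupled):
        records.append((placer.place_anywhere(True), config.condition_a, ""))
    for _ in range(n_unique):
        records.append((placer.place_anywhere(False), config.condition_b, ""))
    for _ in range(config.n_shared_peaks):
        records.append((placer.place_anywhere(False), "shared", ""))

    counters = {config.condition_a: 0, config.condition_b: 0, "shared": 0}
    prefix = {config.condition_a: "uA", config.condition_b: "uB", "shared": "sh"}
    truth_rows = []
    true_ivs = []
    for iv, cond, gene_id in records:
        pid = f"{prefix[cond]}_{counters[cond]:04d}"
        counters[cond] += 1
        true_ivs.append(GenomicInterval(iv.chrom, iv.start, iv.end, name=pid))
        truth_rows.append(
            {
                "peak_id": pid,
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "condition": cond,
                "motif_id": "",
                "implant_offset": -1,
                "implant_strand": "",
                "linked_gene": gene_id,
            }
        )
    truth = pd.DataFrame(truth_rows).sort_values("peak_id").reset_index(drop=True)
    true_set = IntervalSet(true_ivs, label="true_peaks")

    samples = config.sample_layout()
    j = config.boundary_jitter
    sample_peaks: dict[str, IntervalSet] = {}
    for s in samples:
        ivs = []
        for row in truth.itertuples():
            if row.condition not in ("shared", s.condition):
                continue
            ds = int(rng_jitter.integers(-j, j + 1)) if j else 0
            de = int(rng_jitter.integers(-j, j + 1)) if j else 0
            start = max(0, row.start + ds)
            end = min(config.chrom_length, max(start + 1, row.end + de))
            ivs.append(GenomicInterval(row.chrom, start, end, name=row.peak_id))
        sample_peaks[s.sample_id] = IntervalSet(ivs, label=s.sample_id)

    open_mean, closed_mean = config.nb_mean, config.closed_count_mean
    alpha = config.nb_dispersion
    # row order must match the coordinate-sorted IntervalSet, not the truth table
    row_ids = [iv.name for iv in true_set]
    condition_of = truth.set_index("peak_id")["condition"].reindex(row_ids)
    mat = np.zeros((len(row_ids), len(samples)), dtype=np.int64)
    for sj, s in enumerate(samples):
        is_open = (condition_of == "shared") | (condition_of == s.condition)
        means = np.where(is_open, open_mean, closed_mean)
        if alpha < 1e-12:
            mat[:, sj] = rng_counts.poisson(means)
        else:
            r = 1.0 / alpha
            p = 1.0 / (1.0 + alpha * means)
            mat[:, sj] = rng_counts.negative_binomial(r, p)
    counts = CountMatrix(
        true_set,
        samples,
        pd.DataFrame(mat, index=row_ids, columns=[s.sample_id for s in samples]),
    )
    return flagged, sample_peaks, counts, truth


def implant_motifs(
    genome: dict[str, str],
    truth: pd.DataFrame,
    pwm_set: Sequence[PWM],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Write PWM consensus sequences into condition-A-unique peaks.

    ``implant_rate`` of the condition-A-unique peaks receive the consensus
    of a cyclically assigned PWM at a random offset (kept clear of the
    boundary-jitter zone so replicate peak calls always contain the site)
    on a random strand.  Returns the modified genome and updated truth.
    """
    arrays = {c: bytearray(seq, "ascii") for c, seq in genome.items()}
    truth = truth.copy()
    ua = truth.index[truth["condition"] == config.condition_a].to_numpy()
    n_implant = round(config.implant_rate * len(ua))
    chosen = rng.choice(ua, size=n_implant, replace=False) if n_implant else np.array([], int)
    pwms = list(pwm_set)
    margin = config.boundary_jitter
    for rank, idx in enumerate(np.sort(chosen)):
        row = truth.loc[idx]
        pwm = pwms[rank % len(pwms)]
        w = pwm.width
        width = row.end - row.start
        lo, hi = margin, width - w - margin
        if hi < lo:
            logger.warning(
                "PWM %s (width %d) too wide for peak %s; skipped",
                pwm.motif_id, w, row.peak_id,
            )
            continue
        offset = int(rng.integers(lo, hi + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        site = pwm.consensus if strand == "+" else reverse_complement(pwm.consensus)
        pos = row.start + offset
        arrays[row.chrom][pos : pos + w] = site.encode("ascii")
        truth.loc[idx, ["motif_id", "implant_offset", "implant_strand"]] = [
            pwm.motif_id, offset, strand,
        ]
    return {c: bytes(a).decode("ascii") for c, a in arrays.items()}, truth


def generate_expression(
    genes: list[GeneModel],
    flagged: set[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[ExpressionRecord]:
    """One expression row per gene.

    Flagged genes: log2FC from a positively truncated
    Normal(lfc_mean, lfc_sd) and adjusted p uniform below 0.05; all other
    genes: log2FC ~ Normal(0, lfc_sd) and adjusted p uniform in [0.05, 1].
    """
    records = []
    a = -config.lfc_mean / config.lfc_sd
    for g in sorted(genes, key=lambda g: g.gene_id):
        if g.gene_id in flagged:
            lfc = float(
                stats.truncnorm.rvs(a, np.inf, loc=config.lfc_mean, scale=config.lfc_sd,
                                    random_state=rng)
            )
            padj = float(rng.uniform(0.0, 0.05))
        else:
            lfc = float(rng.normal(0.0, config.lfc_sd))
            padj = float(rng.uniform(0.05, 1.0))
        records.append(ExpressionRecord(g.gene_id, lfc, padj))
    return records


def generate_h3k27ac_and_se(
    truth: pd.DataFrame,
    genes: list[GeneModel],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[IntervalSet, IntervalSet, pd.DataFrame]:
    """H3K27ac intervals over condition-A peaks plus super-enhancer clusters.

    ``h3k27ac_coverage`` of the condition-A-unique peaks get a +-500 bp
    H3K27ac pad.  Up to ``n_super_enhancers`` covered peaks that are coupled
    to an upregulated gene additionally get two flanking intervals, forming
    a cluster of >=3 marks within the merge gap; super-enhancers are then
    *derived* from the full H3K27ac set as merged (gap 1000 bp) runs of at
    least three intervals, and recorded in truth with their host gene.
    """
    ua = truth[truth["condition"] == config.condition_a]
    n_cov = round(config.h3k27ac_coverage * len(ua))
    cov_idx = (
        np.sort(rng.choice(ua.index.to_numpy(), size=n_cov, replace=False))
        if n_cov else np.array([], int)
    )
    pads: list[GenomicInterval] = []
    for idx in cov_idx:
        row = truth.loc[idx]
        pads.append(
            GenomicInterval(
                row.chrom,
                max(0, row.start - H3K27AC_PAD),
                min(config.chrom_length, row.end + H3K27AC_PAD),
            )
        )
    covered_coupled = [
        i for i in cov_idx if truth.loc[i, "linked_gene"] != ""
    ]
    se_hosts = covered_coupled[: config.n_super_enhancers]
    extras: list[GenomicInterval] = []
    host_gene_by_peak: dict[str, str] = {}
    for idx in se_hosts:
        row = truth.loc[idx]
        pad_start = max(0, row.start - H3K27AC_PAD)
        pad_end = min(config.chrom_length, row.end + H3K27AC_PAD)
        left_end = pad_start - SE_FLANK_GAP
        right_start = pad_end + SE_FLANK_GAP
        if left_end - SE_FLANK_WIDTH < 0 or right_start + SE_FLANK_WIDTH > config.chrom_length:
            continue
        extras.append(GenomicInterval(row.chrom, left_end - SE_FLANK_WIDTH, left_end))
        extras.append(GenomicInterval(row.chrom, right_start, right_start + SE_FLANK_WIDTH))
        host_gene_by_peak[row.peak_id] = row.linked_gene
    h3k27ac = IntervalSet(pads + extras, label="h3k27ac")
    merged = merge(h3k27ac, max_gap=SE_MERGE_GAP)
    n_members = {(iv.chrom, iv.start, iv.end): 0 for iv in merged}
    for m, _, _ in intersect(merged, h3k27ac):
        n_members[(m.chrom, m.start, m.end)] += 1
    ses = IntervalSet(
        [iv for iv in merged if n_members[(iv.chrom, iv.start, iv.end)] >= 3],
        label="super_enhancers",
    ).with_names("se")

    tss = {g.gene_id: (g.chrom, g.tss) for g in genes}
    se_rows = []
    peak_pos = {r.peak_id: (r.chrom, r.start, r.end) for r in truth.itertuples()}
    for se in ses:
        host = ""
        designed = False
        for pid, gid in host_gene_by_peak.items():
            c, s, e = peak_pos[pid]
            if c == se.chrom and s >= se.start and e <= se.end:
                host = gid
                designed = True
                break
        if not designed and genes:
            # accidental cluster: record the nearest TSS
            cands = [
                (abs((se.start + se.end) // 2 - t), gid)
                for gid, (c, t) in tss.items() if c == se.chrom
            ]
            host = min(cands)[1] if cands else ""
        se_rows.append(
            {
                "se_id": se.name,
                "chrom": se.chrom,
                "start": se.start,
                "end": se.end,
                "gene_id": host,
                "designed": designed,
            }
        )
    truth_se = pd.DataFrame(
        se_rows, columns=["se_id", "chrom", "start", "end", "gene_id", "designed"]
    )
    return h3k27ac, ses, truth_se


def generate_dataset(
    config: SimulationConfig | None = None,
    implant_pwms: Sequence[PWM] | None = None,
) -> SyntheticDataset:
    """Run every generation stage and assemble the full dataset."""
    config = config or SimulationConfig()
    if implant_pwms is None:
        lib = fixture_library()
        implant_pwms = [lib["EBOX_ASCL1"], lib["EBOX_NEUROD1"]]
    rngs = _stage_rngs(config.seed)
    genome, genes = generate_genome(config, rngs["genome"], rngs["genes"])
    flagged, sample_peaks, counts, truth = generate_peaks_and_counts(
        genome, genes, config, rngs["peaks"], rngs["jitter"], rngs["counts"]
    )
    genome, truth = implant_motifs(genome, truth, implant_pwms, config, rngs["implant"])
    flagged_ids = {g.gene_id for g in flagged}
    expression = generate_expression(genes, flagged_ids, config, rngs["expression"])
    h3k27ac, ses, truth_se = generate_h3k27ac_and_se(truth, genes, config, rngs["h3k27ac"])
    return SyntheticDataset(
        config=config,
        genome=genome,
        genes=genes,
        flagged_genes=flagged_ids,
        samples=config.sample_layout(),
        sample_peaks=sample_peaks,
        counts=counts,
        expression=expression,
        h3k27ac=h3k27ac,
        super_enhancers=ses,
        truth_peaks=truth,
        truth_se=truth_se,
    )


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_fasta(genome: Mapping[str, str], path: str | Path, line_width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every component as plain-text standard formats.

    FASTA genome, BED12 gene models, BED6 per-sample peaks / H3K27ac /
    super-enhancers, TSV counts, expression and truth tables.  Output is
    byte-identical for identical seeds.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genome"] = outdir / "genome.fa"
    write_fasta(ds.genome, paths["genome"])
    paths["genes"] = outdir / "genes.bed12"
    write_gene_models_bed12(ds.genes, paths["genes"])
    for sid, peaks in sorted(ds.sample_peaks.items()):
        p = outdir / f"peaks_{sid}.bed"
        write_bed(peaks, p)
        paths[f"peaks_{sid}"] = p
    paths["counts"] = outdir / "counts.tsv"
    ds.counts.write_tsv(paths["counts"])
    paths["expression"] = outdir / "expression.tsv"
    write_expression_table(ds.expression, paths["expression"])
    paths["h3k27ac"] = outdir / "h3k27ac.bed"
    write_bed(ds.h3k27ac, paths["h3k27ac"])
    paths["super_enhancers"] = outdir / "super_enhancers.bed"
    write_bed(ds.super_enhancers, paths["super_enhancers"])
    paths["truth_peaks"] = outdir / "truth_peaks.tsv"
    ds.truth_peaks.to_csv(paths["truth_peaks"], sep="\t", index=False)
    paths["truth_se"] = outdir / "truth_se.tsv"
    ds.truth_se.to_csv(paths["truth_se"], sep="\t", index=False)
    paths["truth_genes"] = outdir / "truth_genes.tsv"
    pd.DataFrame(
        {"gene_id": sorted(g.gene_id for g in ds.genes)}
    ).assign(upregulated=lambda d: d["gene_id"].isin(ds.flagged_genes)).to_csv(
        paths["truth_genes"], sep="\t", index=False
    )
    return paths
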