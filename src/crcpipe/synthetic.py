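"""Synthetic epigenome generator with a planted regulatory circuit.

Emulates the input structure of an H3K27ac ChIP-seq sample around a set of
TF genes: a random genome, TF gene annotation, peak calls, a base-resolution
signal track, and one PWM per TF. A chosen core of TFs receives clustered
high-signal peak domains near their TSSs (the planted super-enhancers), each
carrying embedded motif instances of every core member — a fully
interconnected autoregulatory loop the pipeline should recover. Decoys
comprise near-miss clusters (a clique missing one edge, self-motif count
exactly 2) and singleton low-signal peaks, against background peaks
elsewhere. A truth JSON records everything that was planted.

All randomness flows from one seeded generator, and every writer is
canonical, so identical config+seed reproduces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as cio
from .types import GeneModel, GenomicInterval, Peak, PWMRecord, SignalTrack

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_pwms",
    "sample_motif_instance",
    "plant_epigenome",
]

_REVCOMP = str.maketrans("ACGT", "TGCA")

GENE_SPACING = 120_000  # keeps each TF's SE window free of neighbour TSSs
CLUSTER_MARGIN = 15_000  # > stitch distance: nothing else stitches into a planted SE
SINGLETON_MARGIN = 13_000  # background/singleton peaks stay unstitched singletons


def _revcomp(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


@dataclass
class SyntheticConfig:
    """Study conditions for the planted epigenome.

    Defaults model one sample with a five-TF core circuit among 20 TF genes,
    mirroring the scale of a patient-derived CRC analysis.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_len_bp: int = 2_500_000
    n_tf_genes: int = 20
    k_core: int = 5
    motif_width: int = 8
    motif_dominance: float = 0.95  # dominant-base probability per PWM column
    self_motif_copies: int = 5  # planted copies per (core motif, core SE) pair
    se_peak_cluster: int = 5  # constituent peaks per planted SE
    cluster_gap: int = 600  # intra-cluster gap, well under stitch distance
    cluster_peak_min_bp: int = 300  # MACS2-narrow-like constituent widths
    cluster_peak_max_bp: int = 500
    n_near_miss: int = 3  # decoy cluster TFs (clique minus one edge)
    n_background_peaks: int = 150
    signal_high_median: float = 50.0  # per-bp signal of core SE constituents
    signal_decoy_median: float = 8.0  # per-bp signal of near-miss constituents
    signal_low_median: float = 1.0  # background / singleton peaks
    signal_sigma: float = 0.15  # log-normal sigma for high/decoy draws
    signal_low_sigma: float = 0.3
    gc_content: float = 0.41

    def __post_init__(self) -> None:
        if self.k_core > self.n_tf_genes:
            raise ValueError("k_core must not exceed n_tf_genes")
        if self.self_motif_copies < 3:
            raise ValueError(
                "self_motif_copies must be >= 3 so planted TFs satisfy the "
                "more-than-two self-motif rule"
            )
        if self.motif_width < 4:
            raise ValueError("motif_width must be >= 4")
        if not 0.85 <= self.motif_dominance < 1.0:
            raise ValueError("motif_dominance must be in [0.85, 1)")
        if self.k_core + self.n_near_miss > self.n_tf_genes:
            raise ValueError("core + near-miss TFs exceed n_tf_genes")
        # planted constituents must sit clearly above the background noise
        low_p99 = self.signal_low_median * float(
            np.exp(2.326 * self.signal_low_sigma)
        )
        if self.signal_high_median <= low_p99:
            raise ValueError(
                "signal_high_median must exceed the background 99th percentile"
            )
        capacity = self.n_chroms * (self.chrom_len_bp // GENE_SPACING - 1)
        if capacity < self.n_tf_genes:
            raise ValueError(
                f"genome too small for {self.n_tf_genes} TF genes at "
                f"{GENE_SPACING} bp spacing (capacity {capacity})"
            )


@dataclass
class SyntheticTruth:
    """Everything that was planted, for ground-truthing every stage."""

    core_tfs: list[str]
    near_miss_tfs: list[str]
    singleton_tfs: list[str]
    missing_edge: tuple[str, str] | None
    planted_se: dict[str, tuple[str, int, int]]  # tf -> (chrom, start, end)
    placements: list[dict]  # motif_tf, host_tf, chrom, start, strand
    genes: dict[str, dict]  # symbol -> chrom, tss, strand
    config: dict

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        data = json.loads(Path(path).read_text())
        data["planted_se"] = {
            k: tuple(v) for k, v in data["planted_se"].items()
        }
        if data.get("missing_edge") is not None:
            data["missing_edge"] = tuple(data["missing_edge"])
        return cls(**data)


# ---------------------------------------------------------------------------
# PWMs


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def generate_pwms(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> list[PWMRecord]:
    """One PWM per TF with mutually dissimilar consensus sequences.

    Each column has one dominant base (probability ``motif_dominance``) with
    the remainder split evenly over the other bases — a sharp,
    high-information motif, so a FIMO-style exact p-value threshold of 1e-4
    admits essentially only the consensus word. Consensus sequences (and
    their reverse complements) differ pairwise by at least width/2.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    w = config.motif_width
    min_dist = w // 2
    symbols = [f"TF{i + 1:02d}" for i in range(config.n_tf_genes)]
    taken: list[str] = []
    pwms: list[PWMRecord] = []
    for symbol in symbols:
        for _attempt in range(200):
            consensus = "".join("ACGT"[b] for b in rng.integers(0, 4, size=w))
            rc = _revcomp(consensus)
            if all(
                _hamming(consensus, t) >= min_dist and _hamming(rc, t) >= min_dist
                for t in taken
            ):
                break
        else:
            raise ValueError(
                f"could not draw {config.n_tf_genes} mutually dissimilar "
                f"consensus sequences at width {w}; increase motif_width"
            )
        taken.append(consensus)
        probs = np.full((w, 4), (1.0 - config.motif_dominance) / 3.0)
        for j, base in enumerate(consensus):
            probs[j, "ACGT".index(base)] = config.motif_dominance
        pwms.append(PWMRecord(motif_id=symbol, tf_symbol=symbol, probs=probs))
    return pwms


def sample_motif_instance(pwm: PWMRecord, rng: np.random.Generator) -> str:
    """Draw one instance: per column, consensus with probability 0.9, else a
    base sampled from the column distribution."""
    out = []
    for j in range(pwm.width):
        if rng.random() < 0.9:
            out.append("ACGT"[int(np.argmax(pwm.probs[j]))])
        else:
            out.append("ACGT"[int(rng.choice(4, p=pwm.probs[j]))])
    return "".join(out)


# ---------------------------------------------------------------------------
# epigenome


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> float:
    """Log-normal draw clipped at ±2σ so planted signal tiers never overlap."""
    z = float(np.clip(rng.standard_normal(), -2.0, 2.0))
    return median * float(np.exp(sigma * z))


def _overlaps_any(
    start: int, end: int, occupied: list[tuple[int, int]], margin: int
) -> bool:
    return any(start < e + margin and s - margin < end for s, e in occupied)


def plant_epigenome(
    config: SyntheticConfig, out_dir: str | Path
) -> tuple[SyntheticTruth, dict[str, Path]]:
    """Generate the full synthetic input set and its truth file.

    Writes genome.fa, genes.gtf, peaks.narrowPeak, signal.bedGraph,
    motifs.meme, tf_list.txt and truth.json into ``out_dir`` and returns the
    truth plus a name→path map.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]

    pwms = generate_pwms(config, rng)
    by_symbol = {p.tf_symbol: p for p in pwms}
    symbols = [p.tf_symbol for p in pwms]

    # roles: core circuit, near-miss decoy clusters, singleton decoys
    roles = rng.permutation(config.n_tf_genes)
    core = sorted(symbols[i] for i in roles[: config.k_core])
    near_miss = sorted(
        symbols[i] for i in roles[config.k_core : config.k_core + config.n_near_miss]
    )
    singleton = sorted(
        symbols[i] for i in roles[config.k_core + config.n_near_miss :]
    )
    missing_edge = (near_miss[0], near_miss[1]) if len(near_miss) >= 2 else None

    # genome: i.i.d. bases at the configured GC content
    p_base = np.array(
        [
            (1 - config.gc_content) / 2,
            config.gc_content / 2,
            config.gc_content / 2,
            (1 - config.gc_content) / 2,
        ]
    )
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome: dict[str, bytearray] = {}
    for chrom in chrom_names:
        codes = rng.choice(4, size=config.chrom_len_bp, p=p_base)
        genome[chrom] = bytearray(lut[codes].tobytes())

    # gene placement on a fixed grid, >= GENE_SPACING apart
    slots = [
        (chrom, GENE_SPACING // 2 + i * GENE_SPACING)
        for chrom in chrom_names
        for i in range(config.chrom_len_bp // GENE_SPACING - 1)
    ]
    slot_idx = sorted(rng.choice(len(slots), size=config.n_tf_genes, replace=False))
    genes: list[GeneModel] = []
    gene_info: dict[str, dict] = {}
    for symbol, si in zip(symbols, slot_idx):
        chrom, anchor = slots[si]
        length = int(rng.integers(2_000, 8_001))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            interval = GenomicInterval(chrom, anchor, anchor + length, "+")
        else:
            interval = GenomicInterval(chrom, anchor - length + 1, anchor + 1, "-")
        genes.append(GeneModel(gene_id=symbol, symbol=symbol, interval=interval))
        gene_info[symbol] = {"chrom": chrom, "tss": anchor, "strand": strand}

    peaks: list[Peak] = []
    signal_steps: list[tuple[str, int, int, float]] = []
    # planted clusters repel everything by > stitch distance; other peaks
    # only need to avoid direct overlap
    cluster_zones: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    peak_zones: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    planted_se: dict[str, tuple[str, int, int]] = {}
    cluster_peaks: dict[str, list[Peak]] = {}

    def add_peak(chrom: str, start: int, end: int, name: str, value: float) -> Peak:
        peak = Peak(
            interval=GenomicInterval(chrom, start, end),
            name=name,
            signal_value=round(value, 4),
        )
        peaks.append(peak)
        signal_steps.append((chrom, start, end, round(value, 4)))
        return peak

    # planted clusters for core and near-miss TFs
    for symbol in core + near_miss:
        info = gene_info[symbol]
        chrom, tss = info["chrom"], info["tss"]
        median = (
            config.signal_high_median if symbol in core else config.signal_decoy_median
        )
        widths = [
            int(rng.integers(config.cluster_peak_min_bp, config.cluster_peak_max_bp + 1))
            for _ in range(config.se_peak_cluster)
        ]
        extent = sum(widths) + (config.se_peak_cluster - 1) * config.cluster_gap
        offset = int(rng.integers(4_000, 8_001))
        downstream = bool(rng.random() < 0.5)
        cs = tss + offset if downstream else tss - offset - extent
        cs = max(1_000, min(cs, config.chrom_len_bp - extent - 1_000))
        pos = cs
        members = []
        for k, width in enumerate(widths):
            value = _lognormal(rng, median, config.signal_sigma)
            members.append(
                add_peak(chrom, pos, pos + width, f"se_{symbol}_{k + 1}", value)
            )
            pos += width + config.cluster_gap
        planted_se[symbol] = (chrom, members[0].start, members[-1].end)
        cluster_peaks[symbol] = members
        cluster_zones[chrom].append((members[0].start, members[-1].end))

    # embed motif instances inside the cluster footprints
    placements: list[dict] = []

    def slots_for(members: list[Peak]) -> list[tuple[str, int]]:
        out = []
        step = config.motif_width + 4
        for pk in members:
            p = pk.start + 10
            while p + config.motif_width <= pk.end - 10:
                out.append((pk.chrom, p))
                p += step
        return out

    def embed(motif_tf: str, host_tf: str, copies: int) -> None:
        pool = available[host_tf]
        take = rng.choice(len(pool), size=copies, replace=False)
        chosen = sorted(take.tolist())
        for idx in reversed(chosen):
            chrom, p = pool.pop(idx)
            word = sample_motif_instance(by_symbol[motif_tf], rng)
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = word if strand == "+" else _revcomp(word)
            genome[chrom][p : p + config.motif_width] = inserted.encode("ascii")
            placements.append(
                {
                    "motif_tf": motif_tf,
                    "host_tf": host_tf,
                    "chrom": chrom,
                    "start": p,
                    "strand": strand,
                }
            )

    available = {tf: slots_for(cluster_peaks[tf]) for tf in core + near_miss}
    for host in core:
        for motif_tf in core:
            embed(motif_tf, host, config.self_motif_copies)
    for host in near_miss:
        embed(host, host, 2)  # exactly 2: fails the strict more-than-two rule
        for motif_tf in near_miss:
            if motif_tf == host:
                continue
            if missing_edge and (motif_tf, host) == missing_edge:
                continue
            embed(motif_tf, host, 2)

    # singleton decoys: one low-signal peak near the TSS
    for symbol in singleton:
        info = gene_info[symbol]
        chrom, tss = info["chrom"], info["tss"]
        width = int(rng.integers(400, 901))
        start = tss + int(rng.integers(4_000, 8_001))
        value = _lognormal(rng, config.signal_low_median, config.signal_low_sigma)
        add_peak(chrom, start, start + width, f"single_{symbol}", value)
        peak_zones[chrom].append((start, start + width))

    # background peaks anywhere clear of planted clusters and promoters
    tss_by_chrom: dict[str, list[int]] = {c: [] for c in chrom_names}
    for symbol, info in gene_info.items():
        tss_by_chrom[info["chrom"]].append(info["tss"])
    for k in range(config.n_background_peaks):
        for _attempt in range(1_000):
            chrom = chrom_names[int(rng.integers(0, config.n_chroms))]
            width = int(rng.integers(400, 901))
            start = int(rng.integers(1_000, config.chrom_len_bp - width - 1_000))
            if _overlaps_any(start, start + width, cluster_zones[chrom], CLUSTER_MARGIN):
                continue
            if _overlaps_any(start, start + width, peak_zones[chrom], SINGLETON_MARGIN):
                continue
            mid = start + width // 2
            if any(abs(mid - t) < 5_000 for t in tss_by_chrom[chrom]):
                continue
            break
        else:
            raise ValueError(
                "could not place background peaks; genome too crowded"
            )
        value = _lognormal(rng, config.signal_low_median, config.signal_low_sigma)
        add_peak(chrom, start, start + width, f"bg_{k + 1}", value)
        peak_zones[chrom].append((start, start + width))

    # write all outputs canonically
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
    signal_steps.sort()
    paths = {
        "genome": out_dir / "genome.fa",
        "genes": out_dir / "genes.gtf",
        "peaks": out_dir / "peaks.narrowPeak",
        "signal": out_dir / "signal.bedGraph",
        "motifs": out_dir / "motifs.meme",
        "tf_list": out_dir / "tf_list.txt",
        "truth": out_dir / "truth.json",
    }
    cio.write_fasta(
        {c: genome[c].decode("ascii") for c in chrom_names}, paths["genome"]
    )
    cio.write_gtf_genes(
        sorted(genes, key=lambda g: (g.chrom, g.interval.start)), paths["genes"]
    )
    cio.write_narrowpeak(peaks, paths["peaks"])
    cio.write_bedgraph(SignalTrack.from_records(signal_steps), paths["signal"])
    cio.write_meme_motifs(pwms, paths["motifs"])
    paths["tf_list"].write_text("".join(s + "\n" for s in symbols))

    truth = SyntheticTruth(
        core_tfs=core,
        near_miss_tfs=near_miss,
        singleton_tfs=singleton,
        missing_edge=missing_edge,
        planted_se=planted_se,
        placements=sorted(
            placements,
            key=lambda d: (d["host_tf"], d["motif_tf"], d["chrom"], d["start"]),
        ),
        genes=gene_info,
        config=dataclasses.asdict(config),
    )
    truth.to_json(paths["truth"])
    return truth, paths
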