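"""Synthetic three-species clade with planted repurposing events.

The generator emulates the comparative design the pipeline analyses: a
reference species A carrying enhancer chromatin, a sister species B in
which a subset of orthologous loci gained promoter activity (planted P/E
events), and an outgroup O whose annotations polarize each event.  Per
species it emits genome FASTA, transcript GTF + replicate expression TSV,
DHS and histone-mark replicate peak files, mask BEDs, and pairwise
orthology block maps, together with a ground-truth ledger.

Planted contrasts follow the biology under test: promoter-side elements
receive a configurable CpG gain and a higher downstream U1 site rate than
their orthologous enhancers, with PAS rates mildly reversed; decoy
elements (bivalent loci, truncated isoforms, unstable transcripts)
exercise every filter of the annotation and detection stages.

Geometry: elements sit on a fixed grid of slots (one element per slot,
10 kb pitch) so that the distance-based exclusion rules hold by
construction in the noise-free regime.  All coordinates are shared across
species through identity block maps unless ``block_break_rate`` breaks
them.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import SyntheticConfig
from .genome_io import (
    GenomicInterval,
    OrthologyMap,
    PeakCall,
    TranscriptModel,
    write_intervals,
    write_orthology_map,
    write_sequences,
    write_transcript_models,
)
from .sequence_composition import cpg_frequency, gc_content

__all__ = [
    "PlantedPE",
    "GroundTruth",
    "SpeciesBundle",
    "SyntheticDataset",
    "GenerationError",
    "generate_clade_dataset",
    "mutate_map",
    "write_dataset",
]

SLOT_PITCH = 10_000
SITE_OFFSET = 4_000  # element site within its slot
SITE_WIDTH = 1_000
U1_CONSENSUS = "GTAAGT"
PAS_CONSENSUS = "AATAAA"
MARKS = ("h3k27ac", "h3k4me1", "h3k4me3")


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class PlantedPE:
    pe_id: str
    a_chrom: str
    a_start: int
    a_end: int
    b_chrom: str
    b_tss: int
    strand: str
    b_transcript_id: str
    category: str                 # novel | extended
    ancestral_state: str          # enhancer | promoter | none
    delta_gc: float
    delta_cpg: float
    u1_down_planted_b: int
    u1_down_planted_a: int


@dataclass
class GroundTruth:
    planted_pe: list[PlantedPE] = field(default_factory=list)
    # (chrom, start, end, fate) on species A; fate in
    # {conserved, lost, repurposed} — repurposed enhancers are the P/E set
    ancestral_enhancers: list[tuple[str, int, int, str]] = field(default_factory=list)
    ancestral_promoters: list[tuple[str, int, int, str]] = field(default_factory=list)
    decoys: list[tuple[str, int, int, str]] = field(default_factory=list)


@dataclass
class SpeciesBundle:
    name: str
    sequences: dict[str, str]
    transcripts: list[TranscriptModel]
    dhs: list[GenomicInterval]
    peaks: dict[str, list[list[PeakCall]]]   # mark -> replicates
    masks: list[GenomicInterval]

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    species: dict[str, SpeciesBundle]
    maps: dict[tuple[str, str], OrthologyMap]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# low-level helpers


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> bytearray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=length, p=probs)
    return bytearray(bytes(codes.astype(np.uint8) + 0).translate(
        bytes.maketrans(bytes(range(4)), b"ACGT")
    ))


def _substitute(
    seq: bytearray, rng: np.random.Generator, rate: float, gc: float
) -> None:
    if rate <= 0:
        return
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return
    positions = rng.choice(len(seq), size=n, replace=False)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    letters = b"ACGT"
    for pos, code in zip(positions, rng.choice(4, size=n, p=probs)):
        seq[int(pos)] = letters[int(code)]


_RC = bytes.maketrans(b"ACGT", b"TGCA")


def _write_motif(seq: bytearray, pos: int, motif: str, strand: str) -> None:
    payload = motif.encode() if strand == "+" else motif.encode().translate(_RC)[::-1]
    seq[pos : pos + len(payload)] = payload


def _sense(t: int, strand: str, d0: int, d1: int) -> tuple[int, int]:
    """Absolute [start, end) of sense offsets [d0, d1) downstream of t."""
    if strand == "+":
        return t + d0, t + d1
    return t - d1, t - d0


# ---------------------------------------------------------------------------
# map mutation


def mutate_map(
    map_: OrthologyMap, block_break_rate: float, seed: int | np.random.Generator
) -> OrthologyMap:
    """Fragment a block map, modeling indel divergence.

    Each block is split at Poisson-distributed breakpoints; a short
    deletion is removed from both sides at every break, so the total
    mapped source length never increases.  ``block_break_rate`` is the
    expected number of breaks per base.
    """
    if block_break_rate <= 0:
        return map_
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    blocks = []
    for src, tgt, orient in map_.blocks:
        n_breaks = rng.poisson(block_break_rate * len(src))
        if n_breaks == 0:
            blocks.append((src, tgt, orient))
            continue
        cuts = np.sort(rng.choice(np.arange(1, len(src)), size=min(n_breaks, len(src) - 1), replace=False))
        prev = 0
        segments = []
        for cut in list(cuts) + [len(src)]:
            segments.append((prev, int(cut)))
            prev = int(cut)
        for lo, hi in segments:
            gap = int(rng.integers(1, 30)) if lo > 0 else 0
            lo = min(lo + gap, hi)
            if hi - lo <= 0:
                continue
            s = GenomicInterval(src.seq_name, src.start + lo, src.start + hi)
            if orient == "+":
                t = GenomicInterval(tgt.seq_name, tgt.start + lo, tgt.start + hi)
            else:
                t = GenomicInterval(tgt.seq_name, tgt.end - hi, tgt.end - lo)
            blocks.append((s, t, orient))
    return OrthologyMap(map_.source_assembly, map_.target_assembly, blocks)


# ---------------------------------------------------------------------------
# generator


class _SpeciesDraft:
    def __init__(self, name: str, seqs: dict[str, bytearray]) -> None:
        self.name = name
        self.seqs = seqs
        self.transcripts: list[TranscriptModel] = []
        self.dhs: list[GenomicInterval] = []
        self.peak_sites: dict[str, list[tuple[GenomicInterval, float]]] = {
            m: [] for m in MARKS
        }
        self.masks: list[GenomicInterval] = []
        self.footprints: dict[str, set[int]] = {c: set() for c in seqs}

    def chrom(self, ancestral_chrom: int) -> str:
        return f"{self.name}_chr{ancestral_chrom + 1}"


def _plant_poisson_motifs(
    draft: _SpeciesDraft,
    chrom: str,
    t: int,
    strand: str,
    motif: str,
    rate_per_kb: float,
    side: str,
    rng: np.random.Generator,
) -> int:
    """Plant Poisson-many consensus motifs on a 10-nt grid in the 1-kb
    window up- or downstream (sense) of ``t``; returns the count."""
    n = int(rng.poisson(rate_per_kb))
    if n == 0:
        return 0
    grid = np.arange(0, 994, 10)
    n = min(n, grid.size)
    offsets = rng.choice(grid, size=n, replace=False)
    seq = draft.seqs[chrom]
    planted = 0
    for off in sorted(int(o) for o in offsets):
        d = off if side == "down" else -off - len(motif)
        start, _ = _sense(t, strand, d, d + len(motif))
        if start < 0 or start + len(motif) > len(seq):
            continue
        span = set(range(start, start + len(motif)))
        if span & draft.footprints[chrom]:
            continue
        _write_motif(seq, start, motif, strand)
        draft.footprints[chrom] |= span
        planted += 1
    return planted


def _plant_cpg_shift(
    a: _SpeciesDraft,
    b: _SpeciesDraft,
    chrom_idx: int,
    start: int,
    end: int,
    shift: float,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Write CG dinucleotides into the B-side element until its CpG
    frequency exceeds the A side's by ``shift``.  Returns the achieved
    (ΔGC, ΔCpG)."""
    ca, cb = a.chrom(chrom_idx), b.chrom(chrom_idx)
    a_seq = bytes(a.seqs[ca][start:end]).decode()
    for _ in range(4000):
        b_seq = bytes(b.seqs[cb][start:end]).decode()
        if cpg_frequency(b_seq) - cpg_frequency(a_seq) >= shift:
            break
        pos = start + int(rng.integers(0, end - start - 2))
        if {pos, pos + 1} & b.footprints[cb]:
            continue
        b.seqs[cb][pos : pos + 2] = b"CG"
        b.footprints[cb] |= {pos, pos + 1}
    else:
        raise GenerationError("could not reach the requested CpG shift")
    b_seq = bytes(b.seqs[cb][start:end]).decode()
    return (
        gc_content(b_seq) - gc_content(a_seq),
        cpg_frequency(b_seq) - cpg_frequency(a_seq),
    )


def _add_peak(
    draft: _SpeciesDraft, mark: str, site: GenomicInterval, rng: np.random.Generator
) -> None:
    score = float(rng.uniform(50, 150))
    draft.peak_sites[mark].append((site, score))


def _add_transcript(
    draft: _SpeciesDraft,
    chrom: str,
    t: int,
    strand: str,
    exon_offsets: list[tuple[int, int]],
    tx_id: str,
    gene_id: str,
    fpkm: dict[tuple[str, str], float],
) -> TranscriptModel:
    exons = []
    for d0, d1 in exon_offsets:
        s, e = _sense(t, strand, d0, d1)
        exons.append(GenomicInterval(chrom, s, e, strand))
    tx = TranscriptModel(tx_id, gene_id, exons, fpkm)
    draft.transcripts.append(tx)
    return tx


def _stable_fpkm(
    rng: np.random.Generator, config: SyntheticConfig, organ: str = "liver"
) -> dict[tuple[str, str], float]:
    out: dict[tuple[str, str], float] = {}
    for o in config.organs:
        if o == organ:
            vals = rng.lognormal(
                config.fpkm_lognormal_mu, config.fpkm_lognormal_sigma, config.n_replicates
            )
            if vals.mean() <= 1:  # stability is the planted property
                vals = vals + (1.1 - vals.mean())
        else:
            vals = rng.lognormal(-2.0, 0.3, config.n_replicates)
        for r in range(config.n_replicates):
            out[(o, f"r{r + 1}")] = round(float(vals[r]), 4)
    return out


def _unstable_fpkm(
    rng: np.random.Generator, config: SyntheticConfig
) -> dict[tuple[str, str], float]:
    out: dict[tuple[str, str], float] = {}
    for o in config.organs:
        vals = rng.lognormal(0.0, 0.3, config.n_replicates)
        vals = vals * (0.5 / vals.mean())  # mean pinned below the threshold
        for r in range(config.n_replicates):
            out[(o, f"r{r + 1}")] = round(float(vals[r]), 4)
    return out


def generate_clade_dataset(
    config: SyntheticConfig | None = None, out_dir: str | Path | None = None
) -> SyntheticDataset:
    """Generate the full three-species dataset (and optionally write it).

    Deterministic: identical configs (including the seed) produce
    identical in-memory objects and identical file bytes.
    """
    config = config or SyntheticConfig()
    problems = config.validate()
    if problems:
        raise ValueError("; ".join(problems))
    rng = np.random.default_rng(config.seed)

    # --- slots ------------------------------------------------------------
    slots_per_chrom = max(0, (config.chrom_length - 2000) // SLOT_PITCH)
    slots = [
        (c, 1000 + k * SLOT_PITCH)
        for c in range(config.n_chromosomes)
        for k in range(slots_per_chrom)
    ]
    n_pe = config.n_planted_pe
    n_novel = round(n_pe * config.novel_fraction)
    n_anc_enh_pe = round(n_pe * config.pe_ancestral_enhancer_fraction)
    n_anc_prom_pe = max(0, round(n_pe * config.pe_ancestral_promoter_fraction))
    plain_enh = config.n_enhancers - n_pe - config.n_enh_conserved - config.n_enh_lost
    plain_prom = (
        config.n_promoters
        - config.n_prom_conserved
        - config.n_prom_lost
        - config.n_prom_repurposed
    )
    if plain_enh < 0 or plain_prom < 0:
        raise ValueError("element fate counts exceed n_enhancers/n_promoters")
    roles: list[str] = (
        ["pe"] * n_pe
        + ["enh_conserved"] * config.n_enh_conserved
        + ["enh_lost"] * config.n_enh_lost
        + ["enh_plain"] * plain_enh
        + ["prom_conserved"] * config.n_prom_conserved
        + ["prom_lost"] * config.n_prom_lost
        + ["prom_repurposed"] * config.n_prom_repurposed
        + ["prom_plain"] * plain_prom
        + ["decoy_bivalent"] * config.n_bivalent_decoys
        + ["decoy_truncated"] * config.n_truncated_isoform_decoys
        + ["decoy_unstable"] * config.n_unstable_transcripts
    )
    if len(roles) > len(slots):
        raise GenerationError(
            f"{len(roles)} elements do not fit in {len(slots)} slots; "
            "increase chrom_length or n_chromosomes"
        )
    rng.shuffle(roles)

    # --- genomes ----------------------------------------------------------
    ancestral = [
        _random_sequence(rng, config.chrom_length, config.gc_background)
        for _ in range(config.n_chromosomes)
    ]
    drafts: dict[str, _SpeciesDraft] = {}
    for name in ("A", "B", "O"):
        seqs = {}
        for c in range(config.n_chromosomes):
            seq = bytearray(ancestral[c])
            _substitute(seq, rng, config.substitution_rate, config.gc_background)
            seqs[f"{name}_chr{c + 1}"] = seq
        drafts[name] = _SpeciesDraft(name, seqs)
    a, b, o = drafts["A"], drafts["B"], drafts["O"]

    truth = GroundTruth()
    pe_counter = 0
    tx_counter = 0

    def next_tx(species: str) -> str:
        nonlocal tx_counter
        tx_counter += 1
        return f"{species}_tx{tx_counter:05d}"

    stable_exons = [(0, 1200), (2000, 3500)]

    for (chrom_idx, slot_start), role in zip(slots, roles):
        if role not in (
            "pe", "enh_conserved", "enh_lost", "enh_plain", "prom_conserved",
            "prom_lost", "prom_repurposed", "prom_plain", "decoy_bivalent",
            "decoy_truncated", "decoy_unstable",
        ):
            raise AssertionError(role)
        strand = "+" if rng.random() < 0.5 else "-"
        site_start = slot_start + SITE_OFFSET
        site_end = site_start + SITE_WIDTH
        t = site_end if strand == "+" else site_start  # TSS anchor
        site = {
            sp: GenomicInterval(drafts[sp].chrom(chrom_idx), site_start, site_end)
            for sp in drafts
        }

        if role in ("pe", "enh_conserved", "enh_lost", "enh_plain",
                    "decoy_bivalent", "decoy_truncated"):
            # A-side enhancer chromatin
            a.dhs.append(site["A"])
            _add_peak(a, "h3k27ac", site["A"], rng)
            if rng.random() < 0.34:
                _add_peak(a, "h3k4me1", site["A"], rng)

        if role == "pe":
            pe_counter += 1
            category = "novel" if pe_counter <= n_novel else "extended"
            if pe_counter <= n_anc_enh_pe:
                anc = "enhancer"
            elif pe_counter <= n_anc_enh_pe + n_anc_prom_pe:
                anc = "promoter"
            else:
                anc = "none"
            tx_id = next_tx("B")
            if category == "novel":
                _add_transcript(
                    b, b.chrom(chrom_idx), t, strand, stable_exons, tx_id,
                    f"gene_{tx_id}", _stable_fpkm(rng, config),
                )
            else:
                # shared downstream locus transcribed in both species; the
                # planted transcript is its new 5' isoform
                comp_a = next_tx("A")
                comp_b = next_tx("B")
                comp_tss = t + 1200 if strand == "+" else t - 1200
                _add_transcript(
                    a, a.chrom(chrom_idx), comp_tss, strand,
                    [(0, 1400), (1800, 3000)], comp_a, f"gene_{comp_a}",
                    _stable_fpkm(rng, config),
                )
                _add_transcript(
                    b, b.chrom(chrom_idx), comp_tss, strand,
                    [(0, 1400), (1800, 3000)], comp_b, f"gene_{comp_b}",
                    _stable_fpkm(rng, config),
                )
                _add_transcript(
                    b, b.chrom(chrom_idx), t, strand, [(0, 400), (1200, 2600)],
                    tx_id, f"gene_{comp_b}", _stable_fpkm(rng, config),
                )
            if anc == "enhancer":
                _add_peak(o, "h3k27ac", site["O"], rng)
            elif anc == "promoter":
                o_tx = next_tx("O")
                _add_transcript(
                    o, o.chrom(chrom_idx), t, strand, stable_exons, o_tx,
                    f"gene_{o_tx}", _stable_fpkm(rng, config),
                )
            # motif axis: downstream contrast, matched upstream rates
            u1_b = _plant_poisson_motifs(
                b, b.chrom(chrom_idx), t, strand, U1_CONSENSUS,
                config.u1_downstream_rate_promoter, "down", rng,
            )
            u1_a = _plant_poisson_motifs(
                a, a.chrom(chrom_idx), t, strand, U1_CONSENSUS,
                config.u1_downstream_rate_enhancer, "down", rng,
            )
            for draft, rate in ((b, config.u1_upstream_rate), (a, config.u1_upstream_rate)):
                _plant_poisson_motifs(
                    draft, draft.chrom(chrom_idx), t, strand, U1_CONSENSUS,
                    rate, "up", rng,
                )
            _plant_poisson_motifs(
                b, b.chrom(chrom_idx), t, strand, PAS_CONSENSUS,
                config.pas_rate_promoter, "down", rng,
            )
            _plant_poisson_motifs(
                a, a.chrom(chrom_idx), t, strand, PAS_CONSENSUS,
                config.pas_rate_enhancer, "down", rng,
            )
            for draft in (b, a):
                _plant_poisson_motifs(
                    draft, draft.chrom(chrom_idx), t, strand, PAS_CONSENSUS,
                    config.pas_upstream_rate, "up", rng,
                )
            d_gc, d_cpg = _plant_cpg_shift(
                a, b, chrom_idx, site_start, site_end, config.pe_cpg_shift, rng
            )
            truth.planted_pe.append(
                PlantedPE(
                    f"pe{pe_counter:04d}",
                    a.chrom(chrom_idx), site_start, site_end,
                    b.chrom(chrom_idx), t, strand, tx_id, category, anc,
                    d_gc, d_cpg, u1_b, u1_a,
                )
            )
            if anc == "enhancer":
                truth.ancestral_enhancers.append(
                    (a.chrom(chrom_idx), site_start, site_end, "repurposed")
                )

        elif role in ("enh_conserved", "enh_lost"):
            _add_peak(o, "h3k27ac", site["O"], rng)
            if role == "enh_conserved":
                _add_peak(b, "h3k27ac", site["B"], rng)
                b.dhs.append(site["B"])
            truth.ancestral_enhancers.append(
                (a.chrom(chrom_idx), site_start, site_end,
                 "conserved" if role == "enh_conserved" else "lost")
            )

        elif role == "enh_plain":
            pass

        elif role in ("prom_conserved", "prom_lost", "prom_repurposed", "prom_plain"):
            tx_a = next_tx("A")
            _add_transcript(
                a, a.chrom(chrom_idx), t, strand, stable_exons, tx_a,
                f"gene_{tx_a}", _stable_fpkm(rng, config),
            )
            k4 = GenomicInterval(a.chrom(chrom_idx), t - 500, t + 500)
            _add_peak(a, "h3k4me3", k4, rng)
            if role != "prom_plain":
                o_tx = next_tx("O")
                _add_transcript(
                    o, o.chrom(chrom_idx), t, strand, stable_exons, o_tx,
                    f"gene_{o_tx}", _stable_fpkm(rng, config),
                )
            if role == "prom_conserved":
                tx_b = next_tx("B")
                _add_transcript(
                    b, b.chrom(chrom_idx), t, strand, stable_exons, tx_b,
                    f"gene_{tx_b}", _stable_fpkm(rng, config),
                )
                _add_peak(
                    b, "h3k4me3",
                    GenomicInterval(b.chrom(chrom_idx), t - 500, t + 500), rng,
                )
            elif role == "prom_repurposed":
                _add_peak(b, "h3k27ac", site["B"], rng)
                b.dhs.append(site["B"])
            if role != "prom_plain":
                truth.ancestral_promoters.append(
                    (a.chrom(chrom_idx), site_start, site_end,
                     {"prom_conserved": "conserved", "prom_lost": "lost",
                      "prom_repurposed": "repurposed"}[role])
                )

        elif role == "decoy_bivalent":
            k4_iv_s, k4_iv_e = _sense(t, strand, 500, 1500)
            _add_peak(
                a, "h3k4me3",
                GenomicInterval(a.chrom(chrom_idx), k4_iv_s, k4_iv_e), rng,
            )
            truth.decoys.append(
                (a.chrom(chrom_idx), site_start, site_end, "bivalent")
            )

        elif role == "decoy_truncated":
            # stable isoform pair in B sharing exons; the P/E candidate
            # attaches to the downstream TSS and must be filtered out
            iso1 = next_tx("B")
            iso2 = next_tx("B")
            _add_transcript(
                b, b.chrom(chrom_idx), t, strand, stable_exons, iso1,
                f"gene_{iso1}", _stable_fpkm(rng, config),
            )
            up_tss = t - 2000 if strand == "+" else t + 2000
            _add_transcript(
                b, b.chrom(chrom_idx), up_tss, strand,
                [(0, 1500), (4000, 5200)], iso2, f"gene_{iso1}",
                _stable_fpkm(rng, config),
            )
            truth.decoys.append(
                (a.chrom(chrom_idx), site_start, site_end, "truncated_isoform")
            )

        elif role == "decoy_unstable":
            tx_id = next_tx("B")
            _add_transcript(
                b, b.chrom(chrom_idx), t, strand, stable_exons, tx_id,
                f"gene_{tx_id}", _unstable_fpkm(rng, config),
            )
            truth.decoys.append(
                (a.chrom(chrom_idx), site_start, site_end, "unstable_transcript")
            )

    # masks: a short repeat block at the start of every contig
    for draft in drafts.values():
        for chrom in draft.seqs:
            draft.masks.append(GenomicInterval(chrom, 0, 500, label="repeat"))

    # --- orthology maps ----------------------------------------------------
    maps: dict[tuple[str, str], OrthologyMap] = {}
    for src, tgt in (("A", "B"), ("B", "A"), ("A", "O"), ("B", "O"),
                     ("O", "A"), ("O", "B")):
        blocks = [
            (
                GenomicInterval(f"{src}_chr{c + 1}", 0, config.chrom_length),
                GenomicInterval(f"{tgt}_chr{c + 1}", 0, config.chrom_length),
                "+",
            )
            for c in range(config.n_chromosomes)
        ]
        m = OrthologyMap(src, tgt, blocks)
        if config.block_break_rate > 0:
            m = mutate_map(m, config.block_break_rate, rng)
        maps[(src, tgt)] = m

    # --- replicate peak files ----------------------------------------------
    species: dict[str, SpeciesBundle] = {}
    for name, draft in drafts.items():
        peaks: dict[str, list[list[PeakCall]]] = {}
        for mark in MARKS:
            reps: list[list[PeakCall]] = []
            for _r in range(config.n_replicates):
                rep = []
                for iv, score in draft.peak_sites[mark]:
                    jitter = float(rng.uniform(-5, 5))
                    rep.append(
                        PeakCall(iv, round(score + jitter, 3), len(iv) // 2)
                    )
                reps.append(rep)
            peaks[mark] = reps
        species[name] = SpeciesBundle(
            name,
            {c: bytes(s).decode() for c, s in draft.seqs.items()},
            draft.transcripts,
            sorted(draft.dhs, key=lambda iv: (iv.seq_name, iv.start)),
            peaks,
            draft.masks,
        )

    dataset = SyntheticDataset(config, species, maps, truth)
    if out_dir is not None:
        write_dataset(dataset, out_dir)
    return dataset


# ---------------------------------------------------------------------------
# serialization


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Write the per-species bundle, maps, truth ledger, and manifest."""
    out = Path(out_dir)
    files: list[Path] = []
    for name, bundle in dataset.species.items():
        d = out / name
        d.mkdir(parents=True, exist_ok=True)
        write_sequences(bundle.sequences, d / "genome.fa")
        write_transcript_models(
            bundle.transcripts, d / "transcripts.gtf", d / "expression.tsv"
        )
        write_intervals(bundle.dhs, d / "dhs.bed")
        write_intervals(bundle.masks, d / "masks.bed")
        files += [d / "genome.fa", d / "transcripts.gtf", d / "expression.tsv",
                  d / "dhs.bed", d / "masks.bed"]
        for mark, reps in bundle.peaks.items():
            for r, peaks in enumerate(reps, start=1):
                path = d / f"{mark}_rep{r}.narrowPeak"
                write_intervals(peaks, path)
                files.append(path)
    maps_dir = out / "maps"
    maps_dir.mkdir(parents=True, exist_ok=True)
    for (src, tgt), m in dataset.maps.items():
        path = maps_dir / f"{src}_to_{tgt}.tsv"
        write_orthology_map(m, path)
        files.append(path)

    truth_path = out / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write(
            "record\tpe_id\ta_chrom\ta_start\ta_end\tb_chrom\tb_tss\tstrand\t"
            "b_transcript_id\tcategory\tancestral_state\tdelta_gc\tdelta_cpg\t"
            "u1_down_b\tu1_down_a\tfate\n"
        )
        for pe in dataset.truth.planted_pe:
            fh.write(
                f"pe\t{pe.pe_id}\t{pe.a_chrom}\t{pe.a_start}\t{pe.a_end}\t"
                f"{pe.b_chrom}\t{pe.b_tss}\t{pe.strand}\t{pe.b_transcript_id}\t"
                f"{pe.category}\t{pe.ancestral_state}\t{pe.delta_gc:.6f}\t"
                f"{pe.delta_cpg:.6f}\t{pe.u1_down_planted_b}\t{pe.u1_down_planted_a}\t.\n"
            )
        for kind, rows in (
            ("ancestral_enhancer", dataset.truth.ancestral_enhancers),
            ("ancestral_promoter", dataset.truth.ancestral_promoters),
            ("decoy", dataset.truth.decoys),
        ):
            for chrom, start, end, fate in rows:
                fh.write(
                    f"{kind}\t.\t{chrom}\t{start}\t{end}\t.\t.\t.\t.\t.\t.\t.\t.\t.\t.\t{fate}\n"
                )
    files.append(truth_path)

    manifest = out / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("file\tsha256\n")
        fh.write(f"#seed={dataset.config.seed}\n")
        for path in sorted(files):
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            fh.write(f"{path.relative_to(out)}\t{digest}\n")
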