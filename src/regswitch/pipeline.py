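"""End-to-end orchestration: simulate → annotate → detect → polarize →
compose → motifs → report.

Every stage is a pure function of (inputs, config, seed); the manifest
records content digests so reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .element_annotation import (
    RegulatoryElement,
    call_stable_transcripts,
    call_enhancers,
    define_promoters,
    harmonize_peak_replicates,
    sample_inactive_regions,
    stability_by_organ,
)
from .genome_io import GenomicInterval, TranscriptModel, write_intervals
from .motif_axis import (
    DensityProfile,
    compare_axis_between_species,
    default_pas_matrix,
    default_u1_matrix,
    scan_motif,
    tss_density_profile,
    u1_before_pas_fraction,
)
from .orthology_mapping import project_interval, project_position, reciprocal_ortholog
from .polarization import (
    SpeciesAnnotations,
    assign_outgroup_state,
    define_ancestral_elements,
    repurposing_bias_test,
    tabulate_turnover,
)
from .repurposing_detection import (
    classify_pe_elements,
    count_promoter_orthologous,
    detect_pe_elements,
    filter_truncated_isoform_artifacts,
    pe_vs_inactive_enrichment,
)
from .sequence_composition import (
    cpg_frequency,
    gc_content,
    ortholog_shift_resampling_test,
)
from .synthetic_data import SyntheticDataset, generate_clade_dataset

__all__ = ["SpeciesAnnotation", "PipelineResult", "annotate_species", "run_pipeline"]

_TOP_N_BY_MARK = {"h3k4me3": "k4me3_top_n", "h3k4me1": "k4me1_top_n", "h3k27ac": "k27ac_top_n"}


@dataclass
class SpeciesAnnotation:
    name: str
    consensus_peaks: dict[str, list[GenomicInterval]]
    stable_by_organ: dict[str, set[str]]
    stable_transcripts: list[TranscriptModel]   # stable in the analysis organ
    promoters: list[RegulatoryElement]          # organ-restricted
    enhancers: list[RegulatoryElement]
    inactive: list[RegulatoryElement]

    def polarization_view(self, bundle) -> SpeciesAnnotations:
        return SpeciesAnnotations(
            self.consensus_peaks["h3k27ac"],
            self.consensus_peaks["h3k4me3"],
            bundle.transcripts,
            self.stable_transcripts,
            bundle.contig_lengths,
        )


@dataclass
class PipelineResult:
    config: PipelineConfig
    dataset: SyntheticDataset
    annotations: dict[str, SpeciesAnnotation]
    pe_elements: list
    enrichment: object
    outgroup_states: dict[str, str]       # pe element id -> state (aligned only)
    n_pe_unaligned_outgroup: int
    turnover: object
    bias: dict[str, float]
    shift_test_cpg: object
    shift_test_gc: object
    axis_rows: list[dict]
    u1_before_pas_b: tuple[float, int]
    u1_before_pas_a: tuple[float, int]
    report: dict = field(default_factory=dict)


def annotate_species(
    bundle, config: PipelineConfig, seed: np.random.Generator, organ: str
) -> SpeciesAnnotation:
    """Call promoters, enhancers, and inactive regions for one species."""
    ann = config.annotation
    lengths = bundle.contig_lengths
    consensus = {
        mark: harmonize_peak_replicates(
            reps,
            getattr(ann, _TOP_N_BY_MARK[mark]),
            ann.min_replicates,
            ann.peak_resize,
            lengths,
        )
        for mark, reps in bundle.peaks.items()
    }
    stable_by_organ = stability_by_organ(bundle.transcripts, ann)
    organs_by_tx: dict[str, set[str]] = {}
    for org, ids in stable_by_organ.items():
        for tid in ids:
            organs_by_tx.setdefault(tid, set()).add(org)
    stable = call_stable_transcripts(bundle.transcripts, organ, ann)
    promoters = define_promoters(stable, ann.promoter_window, organs_by_tx, lengths)
    enhancers = call_enhancers(
        bundle.dhs,
        consensus["h3k27ac"],
        consensus["h3k4me1"],
        consensus["h3k4me3"],
        bundle.transcripts,
        config=ann,
        contig_lengths=lengths,
        organs_active={organ},
    )
    exons = [e for tx in bundle.transcripts for e in tx.exons]
    exclusions = (
        list(bundle.dhs)
        + [iv for peaks in consensus.values() for iv in peaks]
    )
    inactive = sample_inactive_regions(
        lengths, exclusions, bundle.masks, ann, seed, exons
    )
    return SpeciesAnnotation(
        bundle.name, consensus, stable_by_organ, stable, promoters, enhancers, inactive
    )


def _fill_composition(elements, sequences) -> None:
    for el in elements:
        seq = sequences[el.interval.seq_name][el.interval.start : el.interval.end]
        el.gc = gc_content(seq)
        el.cpg = cpg_frequency(seq)


def _pair_values(seq_a: str, seq_b: str) -> dict[str, tuple[float, float]]:
    return {
        "gc": (gc_content(seq_a), gc_content(seq_b)),
        "cpg": (cpg_frequency(seq_a), cpg_frequency(seq_b)),
    }


def run_pipeline(
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    dataset: SyntheticDataset | None = None,
) -> PipelineResult:
    """Run the full analysis on a (generated or supplied) clade dataset."""
    config = config or PipelineConfig()
    problems = config.validate()
    if problems:
        raise ValueError("; ".join(problems))
    seeds = np.random.SeedSequence(config.seed).spawn(6)
    rngs = [np.random.default_rng(s) for s in seeds]

    if dataset is None:
        syn = config.synthetic
        syn.seed = config.seed
        dataset = generate_clade_dataset(syn)
    # inactive sampling target follows the synthetic scale unless the
    # annotation config was explicitly lowered
    if config.annotation.inactive_target > 10 * config.synthetic.n_inactive:
        config.annotation.inactive_target = config.synthetic.n_inactive

    organ = config.organ
    annotations = {
        name: annotate_species(bundle, config, rngs[i], organ)
        for i, (name, bundle) in enumerate(dataset.species.items())
    }
    a_ann, b_ann, o_ann = annotations["A"], annotations["B"], annotations["O"]
    map_ab = dataset.maps[("A", "B")]
    map_ba = dataset.maps[("B", "A")]
    map_ao = dataset.maps[("A", "O")]

    # --- detection --------------------------------------------------------
    organs_by_tx_b = {
        tid: {org for org, ids in b_ann.stable_by_organ.items() if tid in ids}
        for tid in {t for ids in b_ann.stable_by_organ.values() for t in ids}
    }
    pe = detect_pe_elements(
        a_ann.enhancers, map_ab, map_ba, b_ann.stable_transcripts, config, organs_by_tx_b
    )
    stable_ids_b = {tx.transcript_id for tx in b_ann.stable_transcripts}
    pe = filter_truncated_isoform_artifacts(
        pe, dataset.species["B"].transcripts, stable_ids_b
    )
    pe = classify_pe_elements(
        pe, map_ba, dataset.species["A"].transcripts,
        dataset.species["B"].transcripts, config.min_match_sister,
    )

    # --- enrichment vs inactive controls ----------------------------------
    _, enh_tested = count_promoter_orthologous(
        [e.interval for e in a_ann.enhancers], map_ab, map_ba,
        b_ann.stable_transcripts, config,
    )
    ctrl_hit, ctrl_tested = count_promoter_orthologous(
        [e.interval for e in a_ann.inactive], map_ab, map_ba,
        b_ann.stable_transcripts, config,
    )
    enrichment = (
        pe_vs_inactive_enrichment(len(pe), enh_tested, ctrl_hit, ctrl_tested)
        if enh_tested and ctrl_tested
        else None
    )

    # --- polarization -----------------------------------------------------
    o_view = o_ann.polarization_view(dataset.species["O"])
    b_view = b_ann.polarization_view(dataset.species["B"])
    outgroup_states: dict[str, str] = {}
    unaligned = 0
    for elem in pe:
        proj = project_interval(
            elem.a_enhancer.interval, map_ao, config.min_match_outgroup
        )
        if proj.target is None:
            unaligned += 1
            continue
        state = assign_outgroup_state(
            proj.target, o_view, config, elem.a_enhancer.element_id
        )
        outgroup_states[elem.a_enhancer.element_id] = state.state

    anc_enh, anc_prom = define_ancestral_elements(
        a_ann.promoters, a_ann.enhancers, map_ab, map_ba, map_ao, o_view, config
    )
    pe_ids = {elem.a_enhancer.element_id for elem in pe}
    turnover = tabulate_turnover(
        anc_enh, anc_prom, map_ab, map_ba, b_view, pe_ids, config
    )
    bias = repurposing_bias_test(turnover) if turnover.enh_total + turnover.prom_total else {}

    # --- composition ------------------------------------------------------
    seq_a = dataset.species["A"].sequences
    seq_b = dataset.species["B"].sequences
    _fill_composition(a_ann.enhancers, seq_a)
    _fill_composition(a_ann.promoters, seq_a)
    _fill_composition(a_ann.inactive, seq_a)

    pe_pairs = {"gc": [], "cpg": []}
    for elem in pe:
        sa = seq_a[elem.a_enhancer.interval.seq_name][
            elem.a_enhancer.interval.start : elem.a_enhancer.interval.end
        ]
        sb = seq_b[elem.b_interval.seq_name][
            elem.b_interval.start : elem.b_interval.end
        ]
        for metric, pair in _pair_values(sa, sb).items():
            pe_pairs[metric].append(pair)
    inactive_pairs = {"gc": [], "cpg": []}
    for el in a_ann.inactive:
        target = reciprocal_ortholog(
            el.interval, map_ab, map_ba, config.min_match_sister
        )
        if target is None:
            continue
        sa = seq_a[el.interval.seq_name][el.interval.start : el.interval.end]
        sb = seq_b[target.seq_name][target.start : target.end]
        for metric, pair in _pair_values(sa, sb).items():
            inactive_pairs[metric].append(pair)

    shift_cpg = shift_gc = None
    if pe_pairs["cpg"] and len(inactive_pairs["cpg"]) > len(pe_pairs["cpg"]):
        shift_cpg = ortholog_shift_resampling_test(
            pe_pairs["cpg"], inactive_pairs["cpg"], config.n_resamples, rngs[3]
        )
        shift_gc = ortholog_shift_resampling_test(
            pe_pairs["gc"], inactive_pairs["gc"], config.n_resamples, rngs[4]
        )

    # --- U1/PAS axis (novel elements only) --------------------------------
    u1, pas = default_u1_matrix(), default_pas_matrix()
    hits: dict[tuple[str, str, str], list] = {}

    def chrom_hits(species: str, chrom: str, matrix) -> list:
        key = (species, chrom, matrix.name)
        if key not in hits:
            hits[key] = scan_motif(
                dataset.species[species].sequences[chrom], matrix, chrom
            )
        return hits[key]

    profiles_a: list[DensityProfile] = []
    profiles_b: list[DensityProfile] = []
    tss_b_list: list[tuple[int, str]] = []
    tss_a_list: list[tuple[int, str]] = []
    by_id_b = {tx.transcript_id: tx for tx in dataset.species["B"].transcripts}
    for elem in pe:
        if elem.category != "novel":
            continue
        tx = by_id_b[elem.b_transcript_id]
        proj = project_position(
            tx.seq_name, tx.tss, map_ba, config.tss_projection_max_shift
        )
        if proj is None:
            continue
        a_chrom, a_tss = proj
        pid = elem.a_enhancer.element_id
        profiles_b.append(
            tss_density_profile(
                tx.tss, tx.strand, chrom_hits("B", tx.seq_name, u1),
                element_id=pid,
                contig_length=len(seq_b[tx.seq_name]),
            )
        )
        profiles_a.append(
            tss_density_profile(
                a_tss, tx.strand, chrom_hits("A", a_chrom, u1),
                element_id=pid,
                contig_length=len(seq_a[a_chrom]),
            )
        )
        tss_b_list.append((tx.tss, tx.strand))
        tss_a_list.append((a_tss, tx.strand))
    axis_rows = (
        compare_axis_between_species(profiles_a, profiles_b, paired=True)
        if len(profiles_a) >= 2
        else []
    )
    # closest-motif ordering: do U1 sites precede a PAS downstream?
    u1_pas_b = u1_pas_a = (float("nan"), 0)
    if tss_b_list:
        u1_pas_b = _pooled_u1_before_pas(pe, by_id_b, "B", u1, pas, chrom_hits)
        u1_pas_a = _pooled_u1_before_pas_a(
            pe, by_id_b, map_ba, config, u1, pas, chrom_hits
        )

    result = PipelineResult(
        config, dataset, annotations, pe, enrichment, outgroup_states, unaligned,
        turnover, bias, shift_cpg, shift_gc, axis_rows, u1_pas_b, u1_pas_a,
    )
    result.report = _build_report(result)
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _pooled_u1_before_pas(pe, by_id_b, species, u1, pas, chrom_hits):
    succ = n = 0
    for elem in pe:
        if elem.category != "novel":
            continue
        tx = by_id_b[elem.b_transcript_id]
        frac, k = u1_before_pas_fraction(
            [(tx.tss, tx.strand)],
            chrom_hits(species, tx.seq_name, u1),
            chrom_hits(species, tx.seq_name, pas),
        )
        if k:
            succ += frac * k
            n += k
    return (succ / n if n else float("nan"), n)


def _pooled_u1_before_pas_a(pe, by_id_b, map_ba, config, u1, pas, chrom_hits):
    succ = n = 0
    for elem in pe:
        if elem.category != "novel":
            continue
        tx = by_id_b[elem.b_transcript_id]
        proj = project_position(
            tx.seq_name, tx.tss, map_ba, config.tss_projection_max_shift
        )
        if proj is None:
            continue
        a_chrom, a_tss = proj
        frac, k = u1_before_pas_fraction(
            [(a_tss, tx.strand)],
            chrom_hits("A", a_chrom, u1),
            chrom_hits("A", a_chrom, pas),
        )
        if k:
            succ += frac * k
            n += k
    return (succ / n if n else float("nan"), n)


def _build_report(result: PipelineResult) -> dict:
    pe = result.pe_elements
    state_counts = {"enhancer": 0, "promoter": 0, "none": 0}
    for state in result.outgroup_states.values():
        state_counts[state] += 1
    report = {
        "n_enhancers_A": len(result.annotations["A"].enhancers),
        "n_promoters_A": len(result.annotations["A"].promoters),
        "n_inactive_A": len(result.annotations["A"].inactive),
        "n_pe": len(pe),
        "n_pe_novel": sum(1 for e in pe if e.category == "novel"),
        "n_pe_extended": sum(1 for e in pe if e.category == "extended"),
        "outgroup_states": state_counts,
        "n_pe_unaligned_outgroup": result.n_pe_unaligned_outgroup,
        "turnover": {
            "counts": result.turnover.counts,
            "enh_total": result.turnover.enh_total,
            "prom_total": result.turnover.prom_total,
        },
        "bias": result.bias,
    }
    if result.enrichment is not None:
        report["enrichment"] = {
            "pe_count": result.enrichment.pe_count,
            "enh_tested": result.enrichment.enh_tested,
            "ctrl_count": result.enrichment.ctrl_count,
            "ctrl_tested": result.enrichment.ctrl_tested,
            "rate_ratio": result.enrichment.rate_ratio,
            "p_value": result.enrichment.p_value,
        }
    if result.shift_test_cpg is not None:
        report["cpg_shift"] = {
            "observed": result.shift_test_cpg.observed_mean_diff,
            "empirical_p": result.shift_test_cpg.empirical_p,
        }
        report["gc_shift"] = {
            "observed": result.shift_test_gc.observed_mean_diff,
            "empirical_p": result.shift_test_gc.empirical_p,
        }
    report["u1_axis"] = [
        {k: row[k] for k in ("side", "window", "mean_a", "mean_b", "p", "p_adj")
         if k in row}
        for row in result.axis_rows
    ]
    report["u1_before_pas"] = {
        "promoter_side_fraction": result.u1_before_pas_b[0],
        "promoter_side_n": result.u1_before_pas_b[1],
        "enhancer_side_fraction": result.u1_before_pas_a[0],
        "enhancer_side_n": result.u1_before_pas_a[1],
    }
    return report


def _write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for name, ann in result.annotations.items():
        d = out / name
        d.mkdir(exist_ok=True)
        write_intervals([e.interval for e in ann.promoters], d / "promoters.bed")
        write_intervals([e.interval for e in ann.enhancers], d / "enhancers.bed")
        write_intervals([e.interval for e in ann.inactive], d / "inactive.bed")
        files += [d / "promoters.bed", d / "enhancers.bed", d / "inactive.bed"]
    pe_path = out / "pe.tsv"
    with open(pe_path, "w") as fh:
        fh.write(
            "a_chrom\ta_start\ta_end\tb_chrom\tb_start\tb_end\t"
            "b_transcript_id\tcategory\torgans_b\toutgroup_state\n"
        )
        for elem in result.pe_elements:
            a, b = elem.a_enhancer.interval, elem.b_interval
            state = result.outgroup_states.get(elem.a_enhancer.element_id, "unaligned")
            fh.write(
                f"{a.seq_name}\t{a.start}\t{a.end}\t{b.seq_name}\t{b.start}\t"
                f"{b.end}\t{elem.b_transcript_id}\t{elem.category}\t"
                f"{','.join(sorted(elem.organs_active_b)) or '.'}\t{state}\n"
            )
    files.append(pe_path)
    report_path = out / "report.json"
    report_path.write_text(json.dumps(result.report, indent=2, sort_keys=True) + "\n")
    files.append(report_path)
    with open(out / "manifest.tsv", "w") as fh:
        fh.write("file\tsha256\n")
        fh.write(f"#seed={result.config.seed}\n")
        for path in sorted(files):
            fh.write(
                f"{path.relative_to(out)}\t"
                f"{hashlib.sha256(path.read_bytes()).hexdigest()}\n"
            )
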