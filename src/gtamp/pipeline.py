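"""End-to-end driver tying the pipeline stages together.

Used by the examples and the validation scripts: simulate a planted study
(reference families plus families withheld from the reference set), run
demultiplexing, frameshift correction, quality filtering, reference-guided
projection and complete-linkage clustering, then score recovery against the
planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cluster import (
    aa_distance_matrix,
    align_to_reference,
    complete_linkage,
    flag_novel,
)
from .framecorrect import AlignmentScoring, CorrectedRead, correct_reads, quality_filter
from .seqio import FusionLayout, PipelineConfig, SequenceRecord
from .simulate import ReferenceSet, SimSpec, default_barcodes, make_reads, make_reference_family
from .primers import ADAPTER_454_A, NIFH_BARCODE_LENGTH, POLF


def nifh_layout() -> FusionLayout:
    """The nifH fusion-read layout: 454 A adapter + 10 bp barcode + PolF."""
    return FusionLayout(
        adapter=ADAPTER_454_A,
        barcode_length=NIFH_BARCODE_LENGTH,
        primer=POLF,
    )


@dataclass
class PlantedRunResult:
    """Outcome of one planted end-to-end run."""

    n_otus: int
    n_novel: int
    n_reads_in: int
    n_reads_passed: int
    frameshift_recovery: float     # fraction of scored reads with exact indel count
    n_scored: int
    corrected: list[CorrectedRead]
    truth: pd.DataFrame


def run_planted_pipeline(
    seed: int,
    n_reference_families: int = 3,
    n_novel_families: int = 2,
    members_per_family: int = 3,
    n_samples: int = 2,
    reads_per_sample: int = 40,
    frameshift_rate: float = 1.0,
    within: float = 0.03,
    between: float = 0.30,
    cutoff: float = 0.05,
    max_truth_indels: int | None = 2,
) -> PlantedRunResult:
    """Simulate, process and cluster one planted community.

    ``n_reference_families`` families contribute both reads and reference
    sequences; ``n_novel_families`` contribute reads only, so their clusters
    should come back flagged novel.  Frameshift recovery is scored on reads
    whose planted indel count is at most ``max_truth_indels``.
    """
    spec = SimSpec(
        n_families=n_reference_families + n_novel_families,
        within_family_divergence=within,
        between_family_divergence=between,
        n_samples=n_samples,
        reads_per_sample=reads_per_sample,
        frameshift_rate=frameshift_rate,
        members_per_family=members_per_family,
        seed=seed,
    )
    refs = make_reference_family(spec)
    known_ids = {rid for rid, fam in refs.family_of.items() if fam < n_reference_families}
    known_prot = [r for r in refs.proteins if r.id in known_ids]
    known_aln = [r for r in refs.alignment if r.id in known_ids]

    layout = nifh_layout()
    barcodes = default_barcodes(n_samples, layout.barcode_length)
    reads, truth = make_reads(spec, refs, layout, barcodes)

    cfg = PipelineConfig()
    from .seqio import demultiplex

    demux = demultiplex(reads, barcodes, layout, cfg)
    trimmed: list[SequenceRecord] = [
        r for sample in sorted(demux.assigned) for r in demux.assigned[sample]
    ]

    scoring = AlignmentScoring()
    corrected = correct_reads(trimmed, known_prot, scoring, denovo=True)
    passed, _ = quality_filter(corrected, cfg)

    truth_by_id = truth.set_index("read_id")
    scored = matched = 0
    for read in passed:
        planted = int(truth_by_id.loc[read.id, "n_indels"])
        if max_truth_indels is not None and planted > max_truth_indels:
            continue
        scored += 1
        if read.n_frameshifts == planted:
            matched += 1

    as_records = [SequenceRecord(id=r.id, seq=r.protein, sample=r.sample) for r in passed]
    projected = align_to_reference(as_records, known_aln)
    cluster_input = projected + known_aln
    dist = aa_distance_matrix(cluster_input)
    clusters = flag_novel(complete_linkage(dist, cutoff), known_ids)

    return PlantedRunResult(
        n_otus=len(clusters),
        n_novel=sum(clusters.novel),
        n_reads_in=len(reads),
        n_reads_passed=len(passed),
        frameshift_recovery=matched / scored if scored else float("nan"),
        n_scored=scored,
        corrected=passed,
        truth=truth,
    )
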