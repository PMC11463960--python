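"""End-to-end genotyping: align -> call edits -> reconstruct alleles ->
classify -> call embryo genotype -> summarize a cohort."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import Scoring, DEFAULT_SCORING, align_read
from .classify import EmbryoGenotype, call_embryo, classify_allele, NO_CALL
from .genome import Amplicon, GuideRNA
from .genotyper import (
    Allele,
    NoCallError,
    call_edits,
    editing_region,
    quals_from_string,
    read_passes_qc,
    reconstruct_alleles,
)
from .simulate import CohortBundle, simulate_reads
from .stats import CohortSummary, summarize


@dataclass(frozen=True)
class GenotyperSettings:
    """Thresholds of the genotyping pipeline with conventional amplicon-QC
    defaults (declared, not inferred from any particular dataset)."""

    region_half_width: int = 10  # nuclease: cut site +/- this many bases
    window_pad: int = 2  # base editor: editing window +/- this many bases
    min_base_q: int = 20
    max_low_q_fraction: float = 0.10
    min_support_reads: int = 5
    min_support_fraction: float = 0.10
    scoring: Scoring = DEFAULT_SCORING


@dataclass
class EmbryoResult:
    embryo_id: str
    genotype: EmbryoGenotype
    alleles: list[Allele]
    n_reads: int
    n_passing: int


def genotype_embryo(
    reads: list[tuple[str, str, str]],
    amplicon: Amplicon,
    guide: GuideRNA,
    scheme: str = "nuclease",
    settings: GenotyperSettings = GenotyperSettings(),
    embryo_id: str = "embryo",
    _aln_cache: dict | None = None,
) -> EmbryoResult:
    """Genotype one embryo from its amplicon reads.

    ``_aln_cache`` maps read sequence -> alignment; alignments depend only on
    the sequence, so the cache can be shared across embryos of a cohort.
    """
    region = editing_region(
        guide,
        scheme,
        half_width=settings.region_half_width,
        window_pad=settings.window_pad,
    )
    cache = _aln_cache if _aln_cache is not None else {}
    edit_lists = []
    for _, seq, qual in reads:
        quals = quals_from_string(qual)
        if len(quals) != len(seq):
            raise ValueError(f"{embryo_id}: quality/sequence length mismatch")
        if not read_passes_qc(quals, settings.min_base_q, settings.max_low_q_fraction):
            continue
        if seq not in cache:
            cache[seq] = align_read(seq, amplicon.sequence, settings.scoring)
        aln = cache[seq]
        if aln is None:  # unalignable (all-N) read
            continue
        edit_lists.append(
            call_edits(aln, seq, quals, amplicon.sequence, region, settings.min_base_q)
        )
    try:
        alleles = reconstruct_alleles(
            edit_lists,
            amplicon,
            settings.min_support_reads,
            settings.min_support_fraction,
        )
    except NoCallError:
        return EmbryoResult(
            embryo_id,
            EmbryoGenotype(NO_CALL, (), scheme),
            [],
            len(reads),
            len(edit_lists),
        )
    classes = tuple(classify_allele(a, amplicon) for a in alleles)
    genotype = call_embryo(classes, scheme)
    return EmbryoResult(embryo_id, genotype, alleles, len(reads), len(edit_lists))


def genotype_cohort(
    reads_by_embryo: dict[str, list[tuple[str, str, str]]],
    amplicon: Amplicon,
    guide: GuideRNA,
    scheme: str = "nuclease",
    settings: GenotyperSettings = GenotyperSettings(),
) -> tuple[list[EmbryoResult], CohortSummary]:
    if not reads_by_embryo:
        raise ValueError("no embryos to genotype")
    cache: dict = {}
    results = [
        genotype_embryo(
            reads, amplicon, guide, scheme, settings, embryo_id=eid, _aln_cache=cache
        )
        for eid, reads in reads_by_embryo.items()
    ]
    summary = summarize([r.genotype.call for r in results])
    return results, summary


def run_cohort(
    bundle: CohortBundle, settings: GenotyperSettings = GenotyperSettings()
) -> tuple[list[EmbryoResult], CohortSummary]:
    """Simulate a cohort bundle and genotype it."""
    reads = simulate_reads(bundle.config, bundle.amplicon)
    return genotype_cohort(
        reads, bundle.amplicon, bundle.guide, bundle.scheme, settings
    )


def allele_report(results: list[EmbryoResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for i, a in enumerate(r.alleles):
            rows.append(
                {
                    "embryo_id": r.embryo_id,
                    "allele_id": f"{r.embryo_id}.a{i}",
                    "edits": a.hgvs(),
                    "support_reads": a.support_reads,
                    "support_fraction": round(a.support_fraction, 4),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["embryo_id", "allele_id", "edits", "support_reads",
                 "support_fraction"],
    )


def genotype_report(results: list[EmbryoResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "embryo_id": r.embryo_id,
                "call": r.genotype.call,
                "n_alleles": len(r.alleles),
                "classes": ",".join(c.value for c in r.genotype.allele_classes),
                "support_fractions": ",".join(
                    f"{a.support_fraction:.3f}" for a in r.alleles
                ),
                "n_reads": r.n_reads,
                "n_passing": r.n_passing,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["embryo_id", "call", "n_alleles", "classes",
                 "support_fractions", "n_reads", "n_passing"],
    )
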