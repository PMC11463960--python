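"""Synthetic mosaic-embryo cohorts and error-bearing amplicon reads.

The generator emulates the statistical structure the genotyper assumes:
each embryo is a mosaic of 1-4 alleles (WT, in-frame indel, frame-disrupting
indel, or C->T stop conversion) mixed at fixed fractions; reads are
single-end full-amplicon copies of an allele corrupted by independent
per-base substitution and single-base indel sequencing errors. Base
qualities are Phred+33 with error-free bases at Q37 and error-injected
bases at Q12, so the genotyper's quality filter sees an honest signal.

``paper_cohorts`` returns deterministic cohort fixtures whose genotype
compositions reproduce published embryo counts for a TEAD4 knockout study:
bovine blastocysts at day 8 (33 embryos: 2 WT, 17 IF, 14 KO), spherical
conceptuses at day 12 (45: 0/22/23), tubular conceptuses at embryonic day
14 (26: 3/10/13), and rabbit day-5 blastocysts edited with a cytosine base
editor (10 embryos: 8 KO, 2 heterozygous).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import fixtures
from .genome import Amplicon, GuideRNA, TranscriptModel
from .genotyper import Edit, apply_edits, left_normalize

Q_GOOD = 37
Q_ERR = 12
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class AlleleSpec:
    """Declarative description of one planted allele."""

    kind: str  # "wt" | "insertion" | "deletion" | "c_to_t"
    position: int = 0
    payload: str | int = ""  # inserted sequence or deleted length
    intended_class: str = "WT"  # WT | IF | KO

    def to_edits(self, amplicon: Amplicon) -> tuple[Edit, ...]:
        """Left-normalized edits this allele carries."""
        if self.kind == "wt":
            return ()
        if self.kind == "insertion":
            e = Edit(self.position, "ins", seq=str(self.payload))
        elif self.kind == "deletion":
            e = Edit(self.position, "del", length=int(self.payload))
        elif self.kind == "c_to_t":
            if amplicon.sequence[self.position] != "C":
                raise ValueError(
                    f"c_to_t at {self.position}: reference base is "
                    f"{amplicon.sequence[self.position]}, not C"
                )
            e = Edit(self.position, "sub", seq="T")
        else:
            raise ValueError(f"unknown allele kind {self.kind!r}")
        return (left_normalize(e, amplicon.sequence),)


def build_allele_sequence(amplicon: Amplicon, spec: AlleleSpec) -> str:
    """The amplicon sequence with the allele's edit applied."""
    edits = spec.to_edits(amplicon)
    for e in edits:
        a, b = e.footprint()
        if not (0 <= a and b <= len(amplicon)):
            raise ValueError(f"edit {e} outside amplicon")
    return apply_edits(amplicon.sequence, edits)


@dataclass(frozen=True)
class EmbryoSpec:
    id: str
    alleles: tuple[tuple[AlleleSpec, float], ...]
    true_genotype: str  # WT | IF | Hz | KO

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValueError(f"{self.id}: at least one allele is required")
        total = sum(f for _, f in self.alleles)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.id}: mixing fractions sum to {total}, not 1")


@dataclass(frozen=True)
class CohortConfig:
    name: str
    embryos: tuple[EmbryoSpec, ...]
    reads_per_embryo: int = 200
    sub_error: float = 0.002
    indel_error: float = 1e-4
    read_length: int | None = None  # None = full allele sequence
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reads_per_embryo < 1:
            raise ValueError("reads_per_embryo must be positive")
        for rate in (self.sub_error, self.indel_error):
            if not 0 <= rate <= 0.1:
                raise ValueError("error rates must lie in [0, 0.1]")


def _corrupt(seq: str, sub_p: float, indel_p: float, rng) -> tuple[str, str]:
    """Apply the sequencing error model; returns (sequence, quality string)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    qual = np.full(arr.size, Q_GOOD, dtype=np.int16)
    if sub_p > 0:
        hit = np.nonzero(rng.random(arr.size) < sub_p)[0]
        for i in hit:
            choices = _BASES[_BASES != arr[i]]
            arr[i] = rng.choice(choices)
            qual[i] = Q_ERR
    out_seq = arr.tobytes().decode()
    out_q = "".join(chr(q + 33) for q in qual)
    if indel_p > 0:
        hit = np.nonzero(rng.random(len(out_seq)) < indel_p)[0]
        for i in sorted(hit, reverse=True):
            if rng.random() < 0.5:  # single-base insertion before i
                b = chr(rng.choice(_BASES))
                out_seq = out_seq[:i] + b + out_seq[i:]
                out_q = out_q[:i] + chr(Q_ERR + 33) + out_q[i:]
            else:  # single-base deletion of i
                out_seq = out_seq[:i] + out_seq[i + 1 :]
                out_q = out_q[:i] + out_q[i + 1 :]
    return out_seq, out_q


def simulate_reads(
    config: CohortConfig, amplicon: Amplicon
) -> dict[str, list[tuple[str, str, str]]]:
    """Simulate reads for every embryo: ``{embryo_id: [(read_id, seq, qual)]}``.

    A fixed config (including seed) yields byte-identical output.
    """
    out: dict[str, list[tuple[str, str, str]]] = {}
    for k, embryo in enumerate(config.embryos):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(k,))
        )
        allele_seqs = [
            build_allele_sequence(amplicon, spec) for spec, _ in embryo.alleles
        ]
        fractions = np.array([f for _, f in embryo.alleles])
        reads = []
        for r in range(config.reads_per_embryo):
            ai = int(rng.choice(len(allele_seqs), p=fractions))
            seq = allele_seqs[ai]
            if config.read_length is not None:
                seq = seq[: config.read_length]
            seq, qual = _corrupt(seq, config.sub_error, config.indel_error, rng)
            reads.append((f"{embryo.id}:read{r}", seq, qual))
        out[embryo.id] = reads
    return out


# ---------------------------------------------------------------------------
# published cohort fixtures


@dataclass(frozen=True)
class CohortBundle:
    """Everything needed to simulate and genotype one cohort."""

    config: CohortConfig
    amplicon: Amplicon
    guide: GuideRNA
    transcript: TranscriptModel
    scheme: str  # "nuclease" | "base_editor"

    @property
    def truth(self) -> dict[str, str]:
        return {e.id: e.true_genotype for e in self.config.embryos}


def _wt_allele() -> AlleleSpec:
    return AlleleSpec("wt")


def _bovine_alleles() -> dict[str, AlleleSpec]:
    f = fixtures
    return {
        "IF": AlleleSpec("insertion", f.BOVINE_IF_EDIT.pos, f.BOVINE_IF_EDIT.seq, "IF"),
        "KO1": AlleleSpec("insertion", f.BOVINE_KO1_EDIT.pos, f.BOVINE_KO1_EDIT.seq, "KO"),
        "KO2": AlleleSpec("deletion", f.BOVINE_KO2_EDIT.pos, f.BOVINE_KO2_EDIT.length, "KO"),
        "KO3": AlleleSpec("deletion", f.BOVINE_KO3_EDIT.pos, f.BOVINE_KO3_EDIT.length, "KO"),
    }


# mosaic allele-mixture patterns; embryos cycle through them so cohorts mix
# pure and multi-allele mosaics (1-4 alleles per embryo)
def _if_patterns(a):
    wt = _wt_allele()
    return [
        ((a["IF"], 1.0),),
        ((wt, 0.4), (a["IF"], 0.6)),
        ((a["IF"], 0.5), (a["KO1"], 0.5)),
        ((wt, 0.25), (a["IF"], 0.25), (a["KO1"], 0.5)),
    ]


def _ko_patterns(a):
    return [
        ((a["KO1"], 1.0),),
        ((a["KO1"], 0.6), (a["KO2"], 0.4)),
        ((a["KO1"], 0.4), (a["KO2"], 0.3), (a["KO3"], 0.3)),
    ]


def _bovine_cohort(
    name: str, n_wt: int, n_if: int, n_ko: int, seed: int, **kwargs
) -> CohortBundle:
    alleles = _bovine_alleles()
    wt = _wt_allele()
    embryos = []
    for i in range(n_wt):
        embryos.append(EmbryoSpec(f"{name}-wt{i:02d}", ((wt, 1.0),), "WT"))
    ifs = _if_patterns(alleles)
    for i in range(n_if):
        embryos.append(EmbryoSpec(f"{name}-if{i:02d}", ifs[i % len(ifs)], "IF"))
    kos = _ko_patterns(alleles)
    for i in range(n_ko):
        embryos.append(EmbryoSpec(f"{name}-ko{i:02d}", kos[i % len(kos)], "KO"))
    config = CohortConfig(name=name, embryos=tuple(embryos), seed=seed, **kwargs)
    return CohortBundle(
        config=config,
        amplicon=fixtures.bovine_amplicon(),
        guide=fixtures.bovine_guide(),
        transcript=fixtures.bovine_transcript(),
        scheme="nuclease",
    )


def _rabbit_cohort(name: str, n_hz: int, n_ko: int, seed: int, **kwargs) -> CohortBundle:
    stop = AlleleSpec(
        "c_to_t", fixtures.RABBIT_STOP_EDIT.pos, intended_class="KO"
    )
    wt = _wt_allele()
    embryos = []
    for i in range(n_ko):
        embryos.append(EmbryoSpec(f"{name}-ko{i:02d}", ((stop, 1.0),), "KO"))
    for i in range(n_hz):
        embryos.append(
            EmbryoSpec(f"{name}-hz{i:02d}", ((wt, 0.5), (stop, 0.5)), "Hz")
        )
    config = CohortConfig(name=name, embryos=tuple(embryos), seed=seed, **kwargs)
    return CohortBundle(
        config=config,
        amplicon=fixtures.rabbit_amplicon(),
        guide=fixtures.rabbit_guide(),
        transcript=fixtures.rabbit_transcript(),
        scheme="base_editor",
    )


COHORT_NAMES = ("bovine-D8", "bovine-D12", "bovine-E14", "rabbit-D5")


def paper_cohorts(seed: int = 0, **kwargs) -> dict[str, CohortBundle]:
    """Deterministic cohort fixtures matching the published genotype counts."""
    return {
        "bovine-D8": _bovine_cohort("bovine-D8", 2, 17, 14, seed, **kwargs),
        "bovine-D12": _bovine_cohort("bovine-D12", 0, 22, 23, seed + 1, **kwargs),
        "bovine-E14": _bovine_cohort("bovine-E14", 3, 10, 13, seed + 2, **kwargs),
        "rabbit-D5": _rabbit_cohort("rabbit-D5", 2, 8, seed + 3, **kwargs),
    }


def truth_table(config: CohortConfig, amplicon: Amplicon) -> list[dict]:
    """Rows for the truth TSV: one row per (embryo, allele)."""
    rows = []
    for embryo in config.embryos:
        for spec, frac in embryo.alleles:
            rows.append(
                {
                    "embryo_id": embryo.id,
                    "allele_json": json.dumps(
                        {
                            "kind": spec.kind,
                            "position": spec.position,
                            "payload": spec.payload,
                            "intended_class": spec.intended_class,
                            "edits": [e.hgvs() for e in spec.to_edits(amplicon)],
                        }
                    ),
                    "fraction": frac,
                    "true_genotype": embryo.true_genotype,
                }
            )
    return rows
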