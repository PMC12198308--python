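"""Synthetic inputs for the abundance-rank and polymorphism screens.

Real inputs to these screens are per-sample kallisto quantifications of
*Streptococcus sanguinis* SK36 transcriptomes and breseq polymorphism calls
— neither reproducible offline.  This module generates structurally
identical stand-ins with known ground truth:

* abundance tables over ~2270 protein-coding genes plus rRNA/sRNA decoys,
  with the focal Obelisk transcript planted at an exact target rank;
* variant call sets with mutations planted on chosen replicate labels of
  chosen sequencing projects (plus independently scattered background
  calls), so the recurrence and confounding screens have a known answer;
* the 1137-nt Obelisk-S.s cDNA sequence, packaged as a FASTA asset.

mRNA counts are drawn from a log-normal — a standard heavy-tailed stand-in
for RNA-seq abundance spread.  The downstream rank statistic is expressly
non-parametric, so this distribution is a testing device, not a model claim.

All generators are pure functions of their spec, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .rank_abundance import AbundanceTable, compute_tpm
from .variant_screen import SampleMeta, VariantCall

__all__ = [
    "OBELISK_FEATURE_ID",
    "OBELISK_SEQUENCE_LENGTH",
    "obelisk_sequence",
    "write_obelisk_fasta",
    "SK36_RNASEQ_SAMPLES",
    "SK36_OBELISK_RANKS",
    "SynthAbundanceSpec",
    "synth_abundance",
    "annotation_from_table",
    "write_annotation_tsv",
    "read_annotation_tsv",
    "PlantedVariant",
    "SynthVariantSpec",
    "synth_variants",
    "default_polymorphism_scenario",
]

OBELISK_FEATURE_ID = "Obelisk_000003|Obelisk-S.s"
OBELISK_SEQUENCE_LENGTH = 1137
_REPLICON = "Obelisk-S.s"


def obelisk_sequence() -> str:
    """The packaged 1137-nt Obelisk-S.s cDNA sequence (A/C/G/T only)."""
    ref = resources.files("obelisktools").joinpath("data/obelisk_ss.fasta")
    with resources.as_file(ref) as path:
        record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq)


def write_obelisk_fasta(path) -> Path:
    """Write the packaged Obelisk-S.s cDNA sequence as a single-record FASTA.

    The record id is ``Obelisk_000003|Obelisk-S.s`` and the sequence is the
    1137-nt cDNA, alphabet {A, C, G, T}.
    """
    path = Path(path)
    record = SeqRecord(Seq(obelisk_sequence()), id=OBELISK_FEATURE_ID, description="")
    SeqIO.write([record], str(path), "fasta")
    return path


def _meta(sample_id, bioproject, condition, replicate_label) -> SampleMeta:
    return SampleMeta(sample_id, bioproject, condition, replicate_label)


#: Provenance layout of the 17 public SK36 wildtype RNA-seq runs the screens
#: are designed around: four NCBI Bioprojects deposited by independent labs,
#: with growth condition and replicate label per run.  Used as the default
#: sample sheet when planting synthetic variants.
SK36_RNASEQ_SAMPLES: tuple[SampleMeta, ...] = (
    _meta("SRR1713039", "PRJNA270301", "BHI media, oxic", "1"),
    _meta("SRR20627698", "PRJNA862079", "TY media + glucose, oxic", "1"),
    _meta("SRR20627697", "PRJNA862079", "TY media + glucose, oxic", "2"),
    _meta("SRR20627696", "PRJNA862079", "TY media + glucose, oxic", "3"),
    _meta("SRR24302371", "PRJNA961761", "ASS media, oxic", "1"),
    _meta("SRR24302370", "PRJNA961761", "ASS media, oxic", "2"),
    _meta("SRR24302369", "PRJNA961761", "ASS media, oxic", "3"),
    _meta("SRR23591557", "PRJNA937727", "CDM + sucrose, oxic", "1"),
    _meta("SRR23591555", "PRJNA937727", "CDM + sucrose, oxic", "2"),
    _meta("SRR23591553", "PRJNA937727", "CDM + sucrose, oxic", "3"),
    _meta("SRR23591551", "PRJNA937727", "CDM + glucose, oxic", "1"),
    _meta("SRR23591549", "PRJNA937727", "CDM + glucose, oxic", "2"),
    _meta("SRR23591547", "PRJNA937727", "CDM + glucose, oxic", "3"),
    _meta("SRR23591545", "PRJNA937727", "CDM + sucrose, anoxic", "2"),
    _meta("SRR23591543", "PRJNA937727", "CDM + sucrose, anoxic", "3"),
    _meta("SRR23591541", "PRJNA937727", "CDM + glucose, anoxic", "2"),
    _meta("SRR23591539", "PRJNA937727", "CDM + glucose, anoxic", "3"),
)

#: Observed rank of the focal transcript among the 2270 protein-coding genes
#: (plus itself: "k of 2271") in each of the 17 public runs.  Used to plant
#: a full study-shaped scenario; worst rank across runs is 16.
SK36_OBELISK_RANKS: Mapping[str, int] = {
    "SRR1713039": 1,
    "SRR20627698": 10,
    "SRR20627697": 6,
    "SRR20627696": 6,
    "SRR24302371": 16,
    "SRR24302370": 13,
    "SRR24302369": 13,
    "SRR23591557": 1,
    "SRR23591555": 1,
    "SRR23591553": 1,
    "SRR23591551": 1,
    "SRR23591549": 1,
    "SRR23591547": 1,
    "SRR23591545": 1,
    "SRR23591543": 1,
    "SRR23591541": 1,
    "SRR23591539": 1,
}


@dataclass(frozen=True)
class SynthAbundanceSpec:
    """Recipe for one synthetic abundance table.

    ``planted_rank`` is the exact competition rank (by est_counts) that the
    focal record should hold among the mRNA features plus itself, in
    [1, n_mrna + 1].  ``lognormal_mu`` / ``lognormal_sigma`` are the
    log-scale location and spread of the mRNA count draw; sigma around 2
    gives the several-orders-of-magnitude spread typical of bacterial
    transcriptomes.  rRNA decoys get counts far above every mRNA (as in
    undepleted total-RNA libraries), so a ranking that failed to exclude
    them would visibly shift.
    """

    n_mrna: int = 2270
    planted_rank: int = 1
    lognormal_mu: float = 5.0
    lognormal_sigma: float = 2.0
    n_rrna: int = 12
    n_srna: int = 50
    seed: int = 0
    sample_id: str = "synthetic_sample"
    focal_id: str = OBELISK_FEATURE_ID

    def __post_init__(self) -> None:
        if self.n_mrna < 1:
            raise ValueError("n_mrna must be >= 1")
        if not 1 <= self.planted_rank <= self.n_mrna + 1:
            raise ValueError(
                f"planted_rank must be in [1, {self.n_mrna + 1}], "
                f"got {self.planted_rank}"
            )
        if not self.lognormal_sigma > 0:
            raise ValueError("lognormal_sigma must be > 0")
        if self.n_rrna < 0 or self.n_srna < 0:
            raise ValueError("decoy counts must be >= 0")


def _effective_length(length: np.ndarray) -> np.ndarray:
    # simple fragment-length surrogate adequate for TPM testing
    return np.maximum(length - 100, 1).astype(float)


def _focal_count_between(sorted_desc: np.ndarray, rank: int, rng) -> float:
    """A count that lands the focal record at exactly ``rank`` among the
    mRNA counts plus itself (competition ranking, descending)."""
    n = sorted_desc.size
    if rank == 1:
        return float(sorted_desc[0] * 1.5)
    if rank == n + 1:
        return float(sorted_desc[-1] * 0.5)
    hi, lo = float(sorted_desc[rank - 2]), float(sorted_desc[rank - 1])
    for _ in range(10):
        candidate = lo + (hi - lo) * rng.uniform(0.25, 0.75)
        if lo < candidate < hi:
            return candidate
    raise ValueError(
        f"cannot place focal count strictly between tied neighbours "
        f"({lo!r}, {hi!r}) for rank {rank}"
    )


def synth_abundance(spec: SynthAbundanceSpec) -> AbundanceTable:
    """Generate one abundance table with the focal feature at a known rank.

    mRNA counts are i.i.d. log-normal draws (continuous, so ties have
    probability zero); the focal count is placed strictly between the
    neighbouring order statistics for its target rank.  rRNA decoys are
    drawn above the mRNA maximum and sRNA decoys from a shifted log-normal,
    so excluded classes genuinely perturb a naive all-feature ranking.
    TPM is computed from the counts and standard effective lengths.
    """
    rng = np.random.default_rng(spec.seed)
    mrna_counts = rng.lognormal(spec.lognormal_mu, spec.lognormal_sigma, spec.n_mrna)
    order = np.sort(mrna_counts)[::-1]
    focal_count = _focal_count_between(order, spec.planted_rank, rng)

    mrna_lengths = rng.integers(150, 4500, spec.n_mrna)
    rrna_lengths = rng.choice([2900, 1540, 120], spec.n_rrna)
    srna_lengths = rng.integers(50, 300, spec.n_srna)
    rrna_counts = order[0] * rng.uniform(5.0, 50.0, spec.n_rrna)
    srna_counts = rng.lognormal(spec.lognormal_mu + 2.0, spec.lognormal_sigma,
                                spec.n_srna)

    feature_id = (
        [f"SSA_{i:04d}" for i in range(1, spec.n_mrna + 1)]
        + [f"rRNA_{i:02d}" for i in range(1, spec.n_rrna + 1)]
        + [f"sRNA_{i:02d}" for i in range(1, spec.n_srna + 1)]
        + [spec.focal_id]
    )
    feature_class = (
        ["mRNA"] * spec.n_mrna
        + ["rRNA"] * spec.n_rrna
        + ["sRNA"] * spec.n_srna
        + ["focal"]
    )
    length = np.concatenate(
        [mrna_lengths, rrna_lengths, srna_lengths, [OBELISK_SEQUENCE_LENGTH]]
    ).astype(int)
    est_counts = np.concatenate(
        [mrna_counts, rrna_counts, srna_counts, [focal_count]]
    )
    data = pd.DataFrame(
        {
            "feature_id": feature_id,
            "feature_class": feature_class,
            "length": length,
            "eff_length": _effective_length(length),
            "est_counts": est_counts,
            "tpm": 0.0,
        }
    )
    table = AbundanceTable(sample_id=spec.sample_id, data=data)
    return compute_tpm(table)


def annotation_from_table(table: AbundanceTable) -> dict[str, str]:
    """Feature-class annotation for every non-focal feature of a table.

    The focal feature is deliberately omitted: readers assign the focal
    class from the requested focal id, not from the annotation.
    """
    return {
        row.feature_id: row.feature_class
        for row in table.data.itertuples(index=False)
        if row.feature_class != "focal"
    }


def write_annotation_tsv(annotation: Mapping[str, str], path) -> None:
    """Write a two-column ``feature_id  feature_class`` annotation TSV."""
    pd.DataFrame(
        {
            "feature_id": list(annotation.keys()),
            "feature_class": list(annotation.values()),
        }
    ).to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path) -> dict[str, str]:
    """Read a two-column ``feature_id  feature_class`` annotation TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != ["feature_id", "feature_class"]:
        raise ValueError(
            f"{path}: expected header ['feature_id', 'feature_class'], "
            f"got {list(df.columns)}"
        )
    return dict(zip(df["feature_id"], df["feature_class"]))


@dataclass(frozen=True)
class PlantedVariant:
    """A variant planted into every sample carrying a target replicate label.

    ``bioproject=None`` plants across all projects; otherwise only samples
    of that project receive the variant.  Frequencies are drawn uniformly
    per sample from ``freq_range``.
    """

    position: int
    ref: str
    alt: str
    gene_context: str = ""
    freq_range: tuple[float, float] = (0.08, 0.11)
    replicate_labels: tuple[str, ...] = ("2",)
    bioproject: str | None = None
    replicon: str = _REPLICON

    def __post_init__(self) -> None:
        lo, hi = self.freq_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"freq_range must be within [0, 1], got {self.freq_range}")
        if self.position < 1:
            raise ValueError("position must be >= 1")

    def targets(self, meta: Sequence[SampleMeta]) -> list[SampleMeta]:
        return [
            m for m in meta
            if m.replicate_label in self.replicate_labels
            and (self.bioproject is None or m.bioproject == self.bioproject)
        ]


@dataclass(frozen=True)
class SynthVariantSpec:
    """Recipe for a synthetic cross-sample variant call set.

    Background calls emulate sample-specific noise: per sample, a Poisson
    number of variants at globally unique positions (so background never
    recurs across samples), with frequencies uniform in
    ``frequency_range_background``.
    """

    meta: tuple[SampleMeta, ...] = SK36_RNASEQ_SAMPLES
    planted: tuple[PlantedVariant, ...] = ()
    background_rate: float = 1.0
    frequency_range_background: tuple[float, float] = (0.05, 0.25)
    replicon_length: int = OBELISK_SEQUENCE_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "meta", tuple(self.meta))
        object.__setattr__(self, "planted", tuple(self.planted))
        lo, hi = self.frequency_range_background
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(
                f"background frequency range must be within [0, 1], "
                f"got {self.frequency_range_background}"
            )
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        labels = {m.replicate_label for m in self.meta}
        for pv in self.planted:
            if not set(pv.replicate_labels) & labels:
                raise ValueError(
                    f"planted labels {pv.replicate_labels} absent from metadata"
                )


_BASES = "ACGT"


def synth_variants(spec: SynthVariantSpec) -> list[VariantCall]:
    """Generate planted + background variant calls, deterministically.

    Planted variants appear in exactly the samples carrying their target
    replicate labels (within their project, if one is named).  Background
    positions are drawn without replacement from the replicon, skipping the
    planted positions, so no background variant can recur across samples.
    """
    rng = np.random.default_rng(spec.seed)
    calls: list[VariantCall] = []
    for pv in spec.planted:
        lo, hi = pv.freq_range
        for m in pv.targets(spec.meta):
            calls.append(
                VariantCall(
                    sample_id=m.sample_id,
                    replicon=pv.replicon,
                    position=pv.position,
                    ref_allele=pv.ref,
                    alt_allele=pv.alt,
                    gene_context=pv.gene_context,
                    frequency=float(rng.uniform(lo, hi)),
                )
            )
    planted_positions = {pv.position for pv in spec.planted}
    free = np.array(
        [p for p in range(1, spec.replicon_length + 1)
         if p not in planted_positions]
    )
    free = rng.permutation(free)
    cursor = 0
    lo, hi = spec.frequency_range_background
    for m in spec.meta:
        for _ in range(int(rng.poisson(spec.background_rate))):
            if cursor >= free.size:
                raise ValueError(
                    "replicon exhausted: lower background_rate or enlarge "
                    "replicon_length"
                )
            position = int(free[cursor])
            cursor += 1
            ref = _BASES[int(rng.integers(4))]
            alt = _BASES[(_BASES.index(ref) + int(rng.integers(1, 4))) % 4]
            calls.append(
                VariantCall(
                    sample_id=m.sample_id,
                    replicon=_REPLICON,
                    position=position,
                    ref_allele=ref,
                    alt_allele=alt,
                    gene_context="background",
                    frequency=float(rng.uniform(lo, hi)),
                )
            )
    return calls


def default_polymorphism_scenario(
    meta: Sequence[SampleMeta] = SK36_RNASEQ_SAMPLES,
    background_rate: float = 1.0,
    seed: int = 0,
) -> SynthVariantSpec:
    """The study-shaped scenario: three planted Obelisk mutations.

    * a synonymous Oblin-1 change (R162R, CGA->CGG) at 8-11% frequency in
      replicates 2 and 3 of the single-condition project PRJNA961761 —
      present in 2 of 3 replicates, but spanning one condition, so not a
      confounding candidate;
    * a synonymous Oblin-1 change (I48I, ATC->ATA) and an intergenic
      substitution downstream of Oblin-1 (+274), both riding replicate
      label "2" across the four growth conditions of PRJNA937727 — the
      replicate-confounded pair the screen should flag.

    Positions 194, 536 and 1014 are the three polymorphic sites on the
    1137-nt replicon; reference bases are taken from the packaged sequence.
    """
    seq = obelisk_sequence()

    def planted(position, codon_change, context, labels, project, freq):
        ref = seq[position - 1]
        alt = codon_change if codon_change != ref else ("T" if ref != "T" else "C")
        return PlantedVariant(
            position=position,
            ref=ref,
            alt=alt,
            gene_context=context,
            freq_range=freq,
            replicate_labels=labels,
            bioproject=project,
        )

    return SynthVariantSpec(
        meta=tuple(meta),
        planted=(
            planted(194, "A", "I48I (ATC → ATA)", ("2",),
                    "PRJNA937727", (0.05, 0.15)),
            planted(536, "G", "R162R (CGA → CGG)", ("2", "3"),
                    "PRJNA961761", (0.08, 0.11)),
            planted(1014, "G", "intergenic (+274)", ("2",),
                    "PRJNA937727", (0.05, 0.15)),
        ),
        background_rate=background_rate,
        seed=seed,
    )
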