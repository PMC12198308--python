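"""Within-host polymorphism screen: frequency filter, recurrence, confounding.

Upstream variant callers run in polymorphism mode (breseq-style) report, per
RNA-seq sample, candidate variants with an allele frequency — the fraction
of mapped reads supporting the variant at that position.  This module takes
those per-sample calls (a minimal TSV dialect, or the RA evidence lines of a
breseq GenomeDiff) and

1. filters them at an allele-frequency threshold (default 5%, inclusive,
   matching the caller's own reporting threshold);
2. tabulates recurrence of each distinct variant across samples; and
3. flags variants whose presence pattern within a sequencing project tracks
   a replicate label across growth conditions — the signature of a shared
   inoculum or batch effect rather than independent parallel mutation.

Variant identity is the key (replicon, position, alt_allele); the
gene-context string is annotation payload, not identity.  Coordinates are
1-based throughout, as in breseq output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantCall",
    "SampleMeta",
    "RecurrenceMatrix",
    "ConfoundingFlag",
    "VARIANT_COLUMNS",
    "METADATA_COLUMNS",
    "read_variant_table",
    "write_variant_tsv",
    "read_sample_metadata",
    "write_metadata_tsv",
    "read_genomediff_ra",
    "frequency_filter",
    "build_recurrence",
    "replicate_confounding_flags",
    "flags_to_frame",
]

VARIANT_COLUMNS = [
    "sample_id", "replicon", "position", "ref", "alt", "gene_context", "frequency",
]
METADATA_COLUMNS = ["sample_id", "bioproject", "condition", "replicate_label"]

DEFAULT_FREQUENCY_THRESHOLD = 0.05


@dataclass(frozen=True)
class VariantCall:
    """One polymorphism observation in one sample (1-based coordinate)."""

    sample_id: str
    replicon: str
    position: int
    ref_allele: str
    alt_allele: str
    gene_context: str
    frequency: float

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(
                f"frequency must be in [0, 1], got {self.frequency}"
            )

    @property
    def key(self) -> tuple[str, int, str]:
        """Identity key (replicon, position, alt_allele)."""
        return (self.replicon, self.position, self.alt_allele)


@dataclass(frozen=True)
class SampleMeta:
    """Sample provenance: sequencing project, growth condition, replicate."""

    sample_id: str
    bioproject: str
    condition: str
    replicate_label: str


def read_variant_table(path) -> list[VariantCall]:
    """Read the variant TSV dialect ``sample_id replicon position ref alt
    gene_context frequency`` (one header line, tab-separated)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != VARIANT_COLUMNS:
        raise ValueError(
            f"{path}: expected header {VARIANT_COLUMNS}, got {list(df.columns)}"
        )
    if df.empty:
        warnings.warn(f"{path}: no variant calls (header only)", stacklevel=2)
        return []
    calls = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2  # header + 1-based
        try:
            position = int(row.position)
            frequency = float(row.frequency)
        except ValueError as exc:
            raise ValueError(f"{path}: malformed value at line {line}: {exc}") from exc
        try:
            calls.append(
                VariantCall(
                    sample_id=row.sample_id,
                    replicon=row.replicon,
                    position=position,
                    ref_allele=row.ref,
                    alt_allele=row.alt,
                    gene_context=row.gene_context,
                    frequency=frequency,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {line}: {exc}") from exc
    return calls


def write_variant_tsv(calls: Sequence[VariantCall], path) -> None:
    """Write calls in the same TSV dialect that :func:`read_variant_table` reads."""
    df = pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "replicon": [c.replicon for c in calls],
            "position": [c.position for c in calls],
            "ref": [c.ref_allele for c in calls],
            "alt": [c.alt_allele for c in calls],
            "gene_context": [c.gene_context for c in calls],
            "frequency": [c.frequency for c in calls],
        },
        columns=VARIANT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_sample_metadata(path) -> list[SampleMeta]:
    """Read sample metadata TSV ``sample_id bioproject condition replicate_label``."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != METADATA_COLUMNS:
        raise ValueError(
            f"{path}: expected header {METADATA_COLUMNS}, got {list(df.columns)}"
        )
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate sample_id(s): {sorted(set(dup))}")
    return [
        SampleMeta(
            sample_id=row.sample_id,
            bioproject=row.bioproject,
            condition=row.condition,
            replicate_label=row.replicate_label,
        )
        for row in df.itertuples(index=False)
    ]


def write_metadata_tsv(meta: Sequence[SampleMeta], path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in meta],
            "bioproject": [m.bioproject for m in meta],
            "condition": [m.condition for m in meta],
            "replicate_label": [m.replicate_label for m in meta],
        },
        columns=METADATA_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_genomediff_ra(path, sample_id: str | None = None) -> list[VariantCall]:
    """Ingest the RA (read-alignment evidence) lines of a breseq GenomeDiff.

    Only RA lines are parsed; every other line type is skipped and counted
    in a log message.  RA fields: type, id, parent-ids, seq_id, position,
    insert_position, ref_base, new_base, then key=value pairs from which
    ``frequency`` is taken (default 1.0 if absent, as for consensus calls).
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    calls: list[VariantCall] = []
    skipped: dict[str, int] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] != "RA":
                skipped[fields[0]] = skipped.get(fields[0], 0) + 1
                continue
            if len(fields) < 8:
                raise ValueError(f"{path}: truncated RA line {lineno}")
            kv = dict(
                f.split("=", 1) for f in fields[8:] if "=" in f
            )
            try:
                calls.append(
                    VariantCall(
                        sample_id=sample_id,
                        replicon=fields[3],
                        position=int(fields[4]),
                        ref_allele=fields[6],
                        alt_allele=fields[7],
                        gene_context=kv.get("gene_name", ""),
                        frequency=float(kv.get("frequency", 1.0)),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: RA line {lineno}: {exc}") from exc
    if skipped:
        logger.info("%s: skipped non-RA lines: %s", path, skipped)
    return calls


def frequency_filter(
    calls: Iterable[VariantCall],
    threshold: float = DEFAULT_FREQUENCY_THRESHOLD,
) -> list[VariantCall]:
    """Retain calls with allele frequency >= threshold (inclusive).

    The default 0.05 mirrors the polymorphism-mode caller's own reporting
    threshold; the comparison is inclusive so a call at exactly 5% is kept.
    Order is preserved and the operation is idempotent.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    return [c for c in calls if c.frequency >= threshold]


@dataclass(frozen=True)
class RecurrenceMatrix:
    """Variant-by-sample frequency matrix with presence derived from it.

    Rows follow first appearance order of variant keys; columns follow the
    metadata order and include samples with zero retained calls.
    """

    variants: tuple[tuple[str, int, str], ...]
    samples: tuple[str, ...]
    frequencies: np.ndarray  # shape (n_variants, n_samples)
    gene_contexts: tuple[str, ...] = ()

    @property
    def presence(self) -> np.ndarray:
        return self.frequencies > 0.0

    @property
    def presence_counts(self) -> np.ndarray:
        """Number of samples carrying each variant."""
        return self.presence.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Frequencies as a DataFrame indexed by 'replicon:position:alt'."""
        index = [f"{r}:{p}:{a}" for r, p, a in self.variants]
        return pd.DataFrame(self.frequencies, index=index, columns=list(self.samples))


def build_recurrence(
    calls: Iterable[VariantCall], meta: Sequence[SampleMeta]
) -> RecurrenceMatrix:
    """Tabulate variant presence/frequency across all samples in ``meta``.

    Every call's sample must appear in the metadata.  If the same variant
    key is reported more than once for one sample, the largest frequency is
    kept.
    """
    samples = tuple(m.sample_id for m in meta)
    col = {s: j for j, s in enumerate(samples)}
    keys: list[tuple[str, int, str]] = []
    contexts: list[str] = []
    row: dict[tuple[str, int, str], int] = {}
    entries: list[tuple[int, int, float]] = []
    for call in calls:
        if call.sample_id not in col:
            raise ValueError(
                f"sample {call.sample_id!r} not present in metadata"
            )
        if call.key not in row:
            row[call.key] = len(keys)
            keys.append(call.key)
            contexts.append(call.gene_context)
        entries.append((row[call.key], col[call.sample_id], call.frequency))
    freq = np.zeros((len(keys), len(samples)))
    for i, j, f in entries:
        freq[i, j] = max(freq[i, j], f)
    return RecurrenceMatrix(
        variants=tuple(keys),
        samples=samples,
        frequencies=freq,
        gene_contexts=tuple(contexts),
    )


@dataclass(frozen=True)
class ConfoundingFlag:
    """A variant whose presence tracks one replicate label across conditions."""

    variant: tuple[str, int, str]
    bioproject: str
    replicate_label: str
    n_conditions: int


def replicate_confounding_flags(
    matrix: RecurrenceMatrix, meta: Sequence[SampleMeta]
) -> list[ConfoundingFlag]:
    """Flag variants whose within-project presence pattern equals one
    replicate label's sample set spanning >= 2 growth conditions.

    Such a pattern is evidence that apparent parallel evolution across
    replicate cultures reflects how the samples were prepared (e.g. a shared
    inoculum for all 'replicate 2' cultures) rather than independent
    mutational events.  A variant present in *all* samples of a project is
    not flagged — its pattern carries no label specificity — and neither is
    a pattern spanning a single condition.
    """
    meta_by_id: Mapping[str, SampleMeta] = {m.sample_id: m for m in meta}
    missing = [s for s in matrix.samples if s not in meta_by_id]
    if missing:
        raise ValueError(f"metadata missing for sample(s): {missing}")
    if len({m.condition for m in meta}) < 2:
        warnings.warn(
            "metadata has a single growth condition; replicate confounding "
            "cannot be detected",
            stacklevel=2,
        )
        return []

    by_project: dict[str, list[str]] = {}
    for s in matrix.samples:
        by_project.setdefault(meta_by_id[s].bioproject, []).append(s)

    flags: list[ConfoundingFlag] = []
    presence = matrix.presence
    for i, variant in enumerate(matrix.variants):
        present = {s for s, p in zip(matrix.samples, presence[i]) if p}
        for project, project_samples in by_project.items():
            pattern = present.intersection(project_samples)
            if not pattern or pattern == set(project_samples):
                continue
            labels = {meta_by_id[s].replicate_label for s in project_samples}
            for label in sorted(labels):
                label_set = {
                    s for s in project_samples
                    if meta_by_id[s].replicate_label == label
                }
                if pattern != label_set:
                    continue
                conditions = {meta_by_id[s].condition for s in pattern}
                if len(conditions) >= 2:
                    flags.append(
                        ConfoundingFlag(
                            variant=variant,
                            bioproject=project,
                            replicate_label=label,
                            n_conditions=len(conditions),
                        )
                    )
    return flags


def flags_to_frame(flags: Sequence[ConfoundingFlag]) -> pd.DataFrame:
    """Tabular flag report (one row per variant x project flag)."""
    return pd.DataFrame(
        {
            "replicon": [f.variant[0] for f in flags],
            "position": [f.variant[1] for f in flags],
            "alt": [f.variant[2] for f in flags],
            "bioproject": [f.bioproject for f in flags],
            "replicate_label": [f.replicate_label for f in flags],
            "n_conditions": [f.n_conditions for f in flags],
        },
        columns=["replicon", "position", "alt", "bioproject",
                 "replicate_label", "n_conditions"],
    )
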