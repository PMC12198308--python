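"""Rank of a focal transcript among protein-coding mRNA abundances.

RNA-seq measures relative, not absolute, abundance, so comparing a focal
transcript (here the Obelisk RNA) across samples sequenced by different labs
with different protocols calls for a non-parametric statistic: its rank among
the host's annotated protein-coding transcripts.  Tables arrive in the
kallisto ``abundance.tsv`` dialect (columns ``target_id length eff_length
est_counts tpm``) plus a feature-class annotation; ribosomal and small RNAs
are excluded from the comparison by default, as are features missing from
the annotation.

Ranking is *competition* ranking on descending abundance: rank 1 is the most
abundant feature and tied features share the smallest applicable rank.  Ties
are essentially impossible on real estimated counts but the rule keeps the
statistic deterministic.
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
    "FEATURE_CLASSES",
    "DEFAULT_EXCLUDE",
    "KALLISTO_COLUMNS",
    "AbundanceRecord",
    "AbundanceTable",
    "RankSummary",
    "read_abundance_table",
    "write_abundance_tsv",
    "compute_tpm",
    "focal_rank",
    "summarize_samples",
    "worst_focal_rank",
    "summaries_to_frame",
]

FEATURE_CLASSES = frozenset({"mRNA", "rRNA", "sRNA", "focal", "other"})
DEFAULT_EXCLUDE = frozenset({"rRNA", "sRNA", "other"})
KALLISTO_COLUMNS = ["target_id", "length", "eff_length", "est_counts", "tpm"]
_METRIC_COLUMNS = {"est_count": "est_counts", "tpm": "tpm"}
_TPM_TOTAL = 1.0e6
_TPM_TOL = 0.1


@dataclass(frozen=True)
class AbundanceRecord:
    """One transcript's abundance in one sample."""

    feature_id: str
    feature_class: str
    length: int
    effective_length: float
    est_count: float
    tpm: float


@dataclass(frozen=True)
class AbundanceTable:
    """Per-sample transcript abundances with feature classes.

    ``data`` holds one row per feature with columns ``feature_id,
    feature_class, length, eff_length, est_counts, tpm``.  Exactly one row
    has class ``focal``; when TPM is populated it sums to 1e6 within 0.1.
    """

    sample_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True)
        required = ["feature_id", "feature_class", "length", "eff_length",
                    "est_counts", "tpm"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"abundance table missing columns {missing}")
        if df["feature_id"].eq("").any() or df["feature_id"].isna().any():
            raise ValueError("feature_id must be non-empty")
        dup = df["feature_id"][df["feature_id"].duplicated()]
        if not dup.empty:
            raise ValueError(f"duplicate feature_id(s): {sorted(set(dup))}")
        bad_class = set(df["feature_class"]) - FEATURE_CLASSES
        if bad_class:
            raise ValueError(f"unknown feature_class(es): {sorted(bad_class)}")
        n_focal = int((df["feature_class"] == "focal").sum())
        if n_focal != 1:
            raise ValueError(
                f"table must contain exactly one focal record, found {n_focal}"
            )
        if (df["est_counts"] < 0).any():
            raise ValueError("est_counts must be >= 0")
        if (df["tpm"] < 0).any():
            raise ValueError("tpm must be >= 0")
        total = float(df["tpm"].sum())
        if total > 0 and abs(total - _TPM_TOTAL) > _TPM_TOL:
            raise ValueError(
                f"populated tpm must sum to 1e6 within {_TPM_TOL}, got {total!r}"
            )
        object.__setattr__(self, "data", df)

    @property
    def focal(self) -> pd.Series:
        return self.data.loc[self.data["feature_class"] == "focal"].iloc[0]

    @property
    def n_features(self) -> int:
        return len(self.data)

    def records(self) -> list[AbundanceRecord]:
        return [
            AbundanceRecord(
                feature_id=row.feature_id,
                feature_class=row.feature_class,
                length=int(row.length),
                effective_length=float(row.eff_length),
                est_count=float(row.est_counts),
                tpm=float(row.tpm),
            )
            for row in self.data.itertuples(index=False)
        ]


@dataclass(frozen=True)
class RankSummary:
    """Focal transcript's rank among the retained features of one sample."""

    sample_id: str
    focal_rank: int
    n_compared: int
    excluded_classes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= self.focal_rank <= self.n_compared:
            raise ValueError(
                f"rank {self.focal_rank} outside [1, {self.n_compared}]"
            )


def read_abundance_table(
    path,
    annotation: Mapping[str, str],
    focal_id: str,
    sample_id: str | None = None,
) -> AbundanceTable:
    """Read a kallisto-dialect ``abundance.tsv`` and attach feature classes.

    Features absent from ``annotation`` get class ``other``; ``focal_id``
    overrides any annotation and must be present in the file.  If
    ``sample_id`` is omitted it is taken from the parent directory when the
    file is named ``abundance.tsv`` (kallisto's per-sample layout),
    otherwise from the file stem.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"target_id": str})
    if list(df.columns) != KALLISTO_COLUMNS:
        raise ValueError(
            f"{path}: expected header {KALLISTO_COLUMNS}, got {list(df.columns)}"
        )
    dup = df["target_id"][df["target_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate feature_id(s): {sorted(set(dup))}")
    for col in ("length", "eff_length", "est_counts", "tpm"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[~np.isfinite(vals) | (vals < 0)]
        if len(bad):
            # +2: one for the header line, one for 1-based numbering
            raise ValueError(
                f"{path}: invalid {col} at line {int(bad[0]) + 2}"
            )
        df[col] = vals
    if focal_id not in set(df["target_id"]):
        raise ValueError(f"{path}: focal feature {focal_id!r} not present")
    classes = df["target_id"].map(lambda fid: annotation.get(fid, "other"))
    classes[df["target_id"] == focal_id] = "focal"
    n_other = int((classes == "other").sum())
    if n_other:
        logger.info("%s: %d feature(s) missing from annotation -> class 'other'",
                    path, n_other)
    if sample_id is None:
        sample_id = path.parent.name if path.name == "abundance.tsv" else path.stem
    data = pd.DataFrame(
        {
            "feature_id": df["target_id"],
            "feature_class": classes,
            "length": df["length"].astype(int),
            "eff_length": df["eff_length"].astype(float),
            "est_counts": df["est_counts"].astype(float),
            "tpm": df["tpm"].astype(float),
        }
    )
    return AbundanceTable(sample_id=sample_id, data=data)


def write_abundance_tsv(table: AbundanceTable, path) -> None:
    """Write a table back out in the kallisto ``abundance.tsv`` dialect."""
    out = pd.DataFrame(
        {
            "target_id": table.data["feature_id"],
            "length": table.data["length"],
            "eff_length": table.data["eff_length"],
            "est_counts": table.data["est_counts"],
            "tpm": table.data["tpm"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def compute_tpm(table: AbundanceTable) -> AbundanceTable:
    """Recompute TPM from counts: tpm_i = 1e6 * rate_i / sum(rate), with
    rate_i = est_counts_i / eff_length_i.

    An all-zero table is not an error: all TPM are defined as 0 and a
    warning is emitted (rank over such a table falls back to the tie rule).
    """
    df = table.data.copy()
    positive = df["est_counts"] > 0
    bad = df.loc[positive & (df["eff_length"] <= 0), "feature_id"]
    if not bad.empty:
        raise ValueError(
            f"zero effective length with positive count: {sorted(bad)}"
        )
    rate = np.where(positive, df["est_counts"] / df["eff_length"].where(df["eff_length"] > 0, 1.0), 0.0)
    total = rate.sum()
    if total == 0:
        warnings.warn(
            f"sample {table.sample_id}: all counts are zero; tpm set to 0",
            stacklevel=2,
        )
        df["tpm"] = 0.0
    else:
        df["tpm"] = _TPM_TOTAL * rate / total
    return AbundanceTable(sample_id=table.sample_id, data=df)


def focal_rank(
    table: AbundanceTable,
    metric: str = "est_count",
    exclude: Iterable[str] = DEFAULT_EXCLUDE,
) -> RankSummary:
    """Competition rank of the focal feature among retained features.

    Retains every record whose class is not in ``exclude`` (default: keep
    mRNA and the focal feature; drop rRNA, sRNA and unannotated features).
    Rank 1 is the most abundant retained feature; ties share the smallest
    applicable rank, so the focal rank is 1 + the number of retained
    features strictly more abundant than it.
    """
    exclude = frozenset(exclude)
    if "focal" in exclude:
        raise ValueError("cannot exclude the focal class from its own ranking")
    unknown = exclude - FEATURE_CLASSES
    if unknown:
        raise ValueError(f"unknown class(es) in exclude: {sorted(unknown)}")
    if metric not in _METRIC_COLUMNS:
        raise ValueError(f"metric must be one of {sorted(_METRIC_COLUMNS)}")
    col = _METRIC_COLUMNS[metric]
    retained = table.data.loc[~table.data["feature_class"].isin(exclude)]
    if retained.empty:
        raise ValueError("no records retained after exclusion")
    focal_value = float(retained.loc[retained["feature_class"] == "focal", col].iloc[0])
    rank = 1 + int((retained[col] > focal_value).sum())
    return RankSummary(
        sample_id=table.sample_id,
        focal_rank=rank,
        n_compared=len(retained),
        excluded_classes=tuple(sorted(exclude)),
    )


def summarize_samples(
    tables: Sequence[AbundanceTable],
    metric: str = "est_count",
    exclude: Iterable[str] = DEFAULT_EXCLUDE,
) -> list[RankSummary]:
    """Per-sample rank summaries in stable input order."""
    if not tables:
        raise ValueError("summarize_samples requires at least one table")
    summaries = []
    for table in tables:
        try:
            summaries.append(focal_rank(table, metric=metric, exclude=exclude))
        except ValueError as exc:
            raise ValueError(f"sample {table.sample_id!r}: {exc}") from exc
    return summaries


def worst_focal_rank(summaries: Sequence[RankSummary]) -> int:
    """Largest (worst) focal rank across samples."""
    if not summaries:
        raise ValueError("no summaries given")
    return max(s.focal_rank for s in summaries)


def summaries_to_frame(
    summaries: Sequence[RankSummary], metric: str = "est_count"
) -> pd.DataFrame:
    """Tabular form: sample_id, focal_rank, n_compared, metric, excluded_classes."""
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in summaries],
            "focal_rank": [s.focal_rank for s in summaries],
            "n_compared": [s.n_compared for s in summaries],
            "metric": metric,
            "excluded_classes": [",".join(s.excluded_classes) for s in summaries],
        }
    )
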