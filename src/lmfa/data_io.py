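"""Reading, validating and summarizing long-format intensive longitudinal data.

Experience-sampling studies produce one row per *completed* measurement
occasion: a subject identifier, J continuous indicators, optionally the time
interval since that subject's previous observed occasion (in a user-chosen
unit such as days or hours), and optional covariate columns.  All model code
in this package consumes the validated :class:`ILDataset` container defined
here, never a raw data frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("lmfa")

__all__ = [
    "ILDataset",
    "DatasetSummary",
    "ValidationError",
    "load_dataset",
    "build_dataset",
    "summarize_dataset",
]


class ValidationError(ValueError):
    """Raised when input data violate the long-format requirements."""


@dataclass
class ILDataset:
    """Validated long-format panel of intensive longitudinal data.

    Rows are grouped by subject and ordered by time within subject.  The
    interval of each subject's first row is undefined (stored as NaN) and is
    never used by any likelihood: intervals are only meaningful *between*
    observed occasions.
    """

    frame: pd.DataFrame
    id_col: str
    indicator_cols: list[str]
    interval_col: str | None = None
    covariate_cols: list[str] = field(default_factory=list)

    # ------------------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def n_indicators(self) -> int:
        return len(self.indicator_cols)

    @property
    def subject_ids(self) -> np.ndarray:
        """Unique subject identifiers in order of first appearance."""
        return self.frame[self.id_col].unique()

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def indicators(self) -> np.ndarray:
        """(N, J) array of indicator values."""
        return self.frame[self.indicator_cols].to_numpy(dtype=float)

    @property
    def intervals(self) -> np.ndarray:
        """(N,) array of intervals; NaN on each subject's first row."""
        return self.frame["_interval"].to_numpy(dtype=float)

    def covariates(self, cols: list[str] | None = None) -> np.ndarray:
        cols = self.covariate_cols if cols is None else cols
        return self.frame[cols].to_numpy(dtype=float)

    def subject_slices(self) -> list[tuple[object, slice]]:
        """Contiguous row slice per subject, in order of appearance."""
        ids = self.frame[self.id_col].to_numpy()
        out = []
        start = 0
        for i in range(1, len(ids) + 1):
            if i == len(ids) or ids[i] != ids[start]:
                out.append((ids[start], slice(start, i)))
                start = i
        return out

    def with_columns(self, new: pd.DataFrame) -> pd.DataFrame:
        """Copy of the underlying frame with extra columns appended.

        Collides are resolved by suffixing ``_new`` with a warning, so the
        original data are never silently overwritten.
        """
        out = self.frame.drop(columns=["_interval"]).copy()
        for name in new.columns:
            target = name
            if target in out.columns:
                target = name + "_new"
                logger.warning("column %r exists; appending as %r", name, target)
            out[target] = new[name].to_numpy()
        return out

    def write_csv(self, path) -> None:
        self.frame.drop(columns=["_interval"]).to_csv(path, index=False)


@dataclass
class DatasetSummary:
    n_subjects: int
    n_observations: int
    mean_occasions: float
    sd_occasions: float
    mean_interval: float
    sd_interval: float
    covariate_means: dict[str, float]
    covariate_sds: dict[str, float]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [
            "Dataset summary",
            "---------------",
            f"Subjects:            {self.n_subjects}",
            f"Total observations:  {self.n_observations}",
            f"Occasions/subject:   mean {self.mean_occasions:.2f}, SD {self.sd_occasions:.2f}",
            f"Interval:            mean {self.mean_interval:.2f}, SD {self.sd_interval:.2f}",
        ]
        for name in self.covariate_means:
            lines.append(
                f"Covariate {name}: mean {self.covariate_means[name]:.2f},"
                f" SD {self.covariate_sds[name]:.2f}"
            )
        return "\n".join(lines)


# ----------------------------------------------------------------------
def build_dataset(
    frame: pd.DataFrame,
    id_col: str,
    indicator_cols: list[str],
    interval_col: str | None = None,
    covariate_cols: list[str] | None = None,
) -> ILDataset:
    """Validate a raw long-format frame and wrap it as an :class:`ILDataset`.

    Raises
    ------
    ValidationError
        On a missing column, a zero or negative interval between consecutive
        occasions of a subject, any missing value in an indicator or
        covariate column, or an empty table.
    """
    covariate_cols = list(covariate_cols or [])
    indicator_cols = list(indicator_cols)
    needed = [id_col] + indicator_cols + covariate_cols
    if interval_col is not None:
        needed.append(interval_col)
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise ValidationError(f"column(s) not found in data: {missing}")
    if len(indicator_cols) < 1:
        raise ValidationError("at least one indicator column is required")
    if len(frame) == 0:
        raise ValidationError("dataset contains no rows")

    frame = frame.loc[:, needed].copy().reset_index(drop=True)

    bad = frame[indicator_cols + covariate_cols].isna()
    if bad.to_numpy().any():
        rows = bad.any(axis=1)
        cols = bad.any(axis=0)
        raise ValidationError(
            "missing values are not supported; found NA in column(s) "
            f"{list(bad.columns[cols])} at row(s) {list(frame.index[rows][:10])}. "
            "Remove occasions with missing indicators (or impute missing "
            "covariates) before loading."
        )

    ids = frame[id_col].to_numpy()
    first = np.ones(len(frame), dtype=bool)
    first[1:] = ids[1:] != ids[:-1]
    # re-occurring id after a different id means the file is not grouped
    seen: set = set()
    for i in np.flatnonzero(first):
        if ids[i] in seen:
            raise ValidationError(
                f"rows of subject {ids[i]!r} are not contiguous; data must be "
                "grouped by subject and ordered by time within subject"
            )
        seen.add(ids[i])

    if interval_col is None:
        logger.info(
            "no interval column supplied; treating occasions as equidistant "
            "(all intervals set to 1)"
        )
        interval = np.ones(len(frame))
    else:
        interval = frame[interval_col].to_numpy(dtype=float)
        nonfirst = ~first
        if np.isnan(interval[nonfirst]).any():
            raise ValidationError(f"missing interval values in {interval_col!r}")
        def _py(v):
            return v.item() if hasattr(v, "item") else v

        neg = nonfirst & (interval < 0)
        if neg.any():
            offenders = [(_py(ids[i]), int(i)) for i in np.flatnonzero(neg)[:10]]
            raise ValidationError(
                "negative intervals found (observations within a subject must "
                f"be ordered by time); offending (subject, row): {offenders}"
            )
        zero = nonfirst & (interval == 0)
        if zero.any():
            offenders = [(_py(ids[i]), int(i)) for i in np.flatnonzero(zero)[:10]]
            raise ValidationError(
                "intervals between consecutive observations of a subject must "
                f"not be zero; offending (subject, row): {offenders}"
            )
    interval = interval.astype(float).copy()
    interval[first] = np.nan
    frame["_interval"] = interval

    used = interval[~first]
    if used.size:
        m = float(np.mean(used))
        if m > 100 or m < 0.01:
            logger.warning(
                "mean interval is %.4g; consider rescaling the time unit "
                "(very large or very small intervals cause numerical problems)",
                m,
            )

    return ILDataset(frame, id_col, indicator_cols, interval_col, covariate_cols)


def load_dataset(
    path,
    id_col: str,
    indicator_cols: list[str],
    interval_col: str | None = None,
    covariate_cols: list[str] | None = None,
) -> ILDataset:
    """Read a comma-delimited file with a header row and validate it."""
    frame = pd.read_csv(path)
    return build_dataset(frame, id_col, indicator_cols, interval_col, covariate_cols)


def summarize_dataset(data: ILDataset) -> DatasetSummary:
    """Descriptive statistics; interval stats use non-first occasions only."""
    counts = data.frame.groupby(data.id_col, sort=False).size().to_numpy()
    iv = data.intervals
    iv = iv[~np.isnan(iv)]
    cov = data.frame[data.covariate_cols]
    return DatasetSummary(
        n_subjects=data.n_subjects,
        n_observations=data.n_rows,
        mean_occasions=float(np.mean(counts)),
        sd_occasions=float(np.std(counts, ddof=1)) if len(counts) > 1 else 0.0,
        mean_interval=float(np.mean(iv)) if iv.size else float("nan"),
        sd_interval=float(np.std(iv, ddof=1)) if iv.size > 1 else 0.0,
        covariate_means={c: float(cov[c].mean()) for c in data.covariate_cols},
        covariate_sds={c: float(cov[c].std(ddof=1)) for c in data.covariate_cols},
    )
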