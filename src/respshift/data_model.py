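"""Canonical containers and tabular I/O for test-session data.

A test session is a person × item matrix of scored binary responses plus a
matching matrix of response times in seconds, optionally accompanied by
person-level covariates (e.g., an external criterion score) and item-level
cognitive-complexity covariates (memory load, unique elements, serial
position). Both matrices share one missingness pattern until a trim induces
extra missingness on the response side.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TestDataset",
    "LogRTMatrix",
    "load_dataset",
    "write_dataset",
    "log_transform",
]


class DataValidationError(ValueError):
    """Raised when input tables violate the dataset contract."""


@dataclass
class TestDataset:
    """Binary accuracy and response-time matrices with covariates.

    Parameters
    ----------
    responses
        Person × item array of 0/1 scores; ``nan`` marks a missing response.
    response_times
        Person × item array of positive seconds; ``nan`` marks missing.
    person_ids, item_ids
        Identifier sequences matching the matrix axes.
    person_covariates
        Optional table indexed by person id (e.g., column ``criterion``).
    item_covariates
        Optional table indexed by item id with columns such as
        ``memory_load``, ``unique_elements`` and ``position`` (1-based
        serial administration index).
    """

    responses: np.ndarray
    response_times: np.ndarray
    person_ids: Sequence[str] = field(default=None)  # type: ignore[assignment]
    item_ids: Sequence[str] = field(default=None)  # type: ignore[assignment]
    person_covariates: pd.DataFrame | None = None
    item_covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        self.response_times = np.asarray(self.response_times, dtype=float)
        if self.responses.ndim != 2:
            raise DataValidationError("responses must be a 2-D person × item matrix")
        if self.responses.shape != self.response_times.shape:
            raise DataValidationError(
                f"shape mismatch: responses {self.responses.shape} vs "
                f"response_times {self.response_times.shape}"
            )
        if self.person_ids is None:
            self.person_ids = [f"p{j + 1}" for j in range(self.n_persons)]
        if self.item_ids is None:
            self.item_ids = [f"i{i + 1}" for i in range(self.n_items)]
        self.person_ids = list(map(str, self.person_ids))
        self.item_ids = list(map(str, self.item_ids))
        if len(self.person_ids) != self.n_persons:
            raise DataValidationError("person_ids length does not match matrix rows")
        if len(self.item_ids) != self.n_items:
            raise DataValidationError("item_ids length does not match matrix columns")
        obs = ~np.isnan(self.responses)
        vals = self.responses[obs]
        if vals.size and not np.isin(vals, (0.0, 1.0)).all():
            raise DataValidationError("responses must be 0, 1 or missing")
        rt_obs = ~np.isnan(self.response_times)
        if (self.response_times[rt_obs] <= 0).any():
            j, i = np.argwhere(rt_obs & ~(self.response_times > 0))[0]
            raise DataValidationError(
                f"non-positive response time at person {self.person_ids[j]}, "
                f"item {self.item_ids[i]}"
            )
        if self.item_covariates is not None and "position" in self.item_covariates:
            pos = np.sort(self.item_covariates["position"].to_numpy())
            if not np.array_equal(pos, np.arange(1, self.n_items + 1)):
                raise DataValidationError(
                    "item position covariate must be a permutation of 1..n_items"
                )

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of cells with an observed response."""
        return ~np.isnan(self.responses)

    def with_mask(self, retain: np.ndarray) -> "TestDataset":
        """Return a copy with non-retained responses set to missing.

        Only the accuracy matrix is masked; response times are left intact so
        the RT model can still be refit on the full record if needed.
        """
        retain = np.asarray(retain, dtype=bool)
        if retain.shape != self.responses.shape:
            raise DataValidationError("mask shape does not match dataset")
        resp = self.responses.copy()
        resp[~retain] = np.nan
        return replace(self, responses=resp)

    def criterion(self, column: str = "criterion") -> np.ndarray:
        if self.person_covariates is None or column not in self.person_covariates:
            raise DataValidationError(f"person covariate {column!r} not available")
        return (
            self.person_covariates.loc[self.person_ids, column].to_numpy(dtype=float)
        )


TestDataset.__test__ = False  # not a test case despite the class name


@dataclass(frozen=True)
class LogRTMatrix:
    """Natural-log response times (missing preserved)."""

    values: np.ndarray

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.values)


def log_transform(rt_matrix: np.ndarray | TestDataset) -> LogRTMatrix:
    """Apply the natural-log transform to a response-time matrix.

    Response-time distributions have a hard floor at zero and a long right
    tail; working on the log scale makes the additive person + item model
    (and its normal residuals) tenable.
    """
    if isinstance(rt_matrix, TestDataset):
        rt = rt_matrix.response_times
    else:
        rt = np.asarray(rt_matrix, dtype=float)
    bad = np.argwhere(~np.isnan(rt) & (rt <= 0))
    if bad.size:
        j, i = bad[0]
        raise DataValidationError(
            f"cannot log-transform non-positive RT at row {j}, column {i}"
        )
    with np.errstate(invalid="ignore"):
        return LogRTMatrix(values=np.log(rt))


def _read_wide(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={0: str})
    df = df.set_index(df.columns[0])
    df.index.name = "person"
    df.columns = df.columns.map(str)
    return df.astype(float)


def _pivot_long(df: pd.DataFrame, value: str) -> pd.DataFrame:
    if df.duplicated(subset=["person", "item"]).any():
        dup = df[df.duplicated(subset=["person", "item"], keep=False)].iloc[0]
        raise DataValidationError(
            f"duplicate (person, item) record: ({dup['person']}, {dup['item']})"
        )
    wide = df.pivot(index="person", columns="item", values=value)
    return wide


def load_dataset(
    responses_path: str | Path,
    rts_path: str | Path | None = None,
    *,
    person_covariates_path: str | Path | None = None,
    item_covariates_path: str | Path | None = None,
    layout: str = "wide",
    column_map: dict[str, str] | None = None,
) -> TestDataset:
    """Read a :class:`TestDataset` from CSV files.

    ``layout="wide"``: first column is the person id, remaining columns are
    item ids; one file for responses, one for response times.
    ``layout="long"``: a single file with columns ``person,item,response,rt``
    (names overridable via ``column_map``); duplicate (person, item) rows are
    rejected.
    """
    responses_path = Path(responses_path)
    if layout == "wide":
        if rts_path is None:
            raise DataValidationError("wide layout requires a response-time file")
        resp = _read_wide(responses_path)
        rts = _read_wide(Path(rts_path))
        if list(resp.columns) != list(rts.columns) or list(resp.index) != list(rts.index):
            raise DataValidationError(
                "response and RT files disagree on person/item identifiers"
            )
    elif layout == "long":
        cmap = {"person": "person", "item": "item", "response": "response", "rt": "rt"}
        cmap.update(column_map or {})
        df = pd.read_csv(responses_path, dtype={cmap["person"]: str, cmap["item"]: str})
        missing_cols = [v for v in cmap.values() if v not in df.columns]
        if missing_cols:
            raise DataValidationError(f"long file lacks columns: {missing_cols}")
        df = df.rename(columns={v: k for k, v in cmap.items()})
        resp = _pivot_long(df, "response")
        rts = _pivot_long(df, "rt")
    else:
        raise DataValidationError(f"unknown layout {layout!r}; use 'wide' or 'long'")

    person_cov = item_cov = None
    if person_covariates_path is not None:
        person_cov = pd.read_csv(person_covariates_path, dtype={0: str})
        person_cov = person_cov.set_index(person_cov.columns[0])
        unknown = set(resp.index) - set(person_cov.index)
        if unknown:
            raise DataValidationError(f"persons without covariates: {sorted(unknown)[:5]}")
    if item_covariates_path is not None:
        item_cov = pd.read_csv(item_covariates_path, dtype={0: str})
        item_cov = item_cov.set_index(item_cov.columns[0])
        unknown = set(resp.columns) - set(item_cov.index)
        if unknown:
            raise DataValidationError(f"items without covariates: {sorted(unknown)[:5]}")

    return TestDataset(
        responses=resp.to_numpy(),
        response_times=rts.to_numpy(),
        person_ids=list(resp.index),
        item_ids=list(resp.columns),
        person_covariates=person_cov,
        item_covariates=item_cov,
    )


def write_dataset(dataset: TestDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write wide-layout CSVs; inverse of :func:`load_dataset`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, mat in ("responses", dataset.responses), ("response_times", dataset.response_times):
        df = pd.DataFrame(mat, index=dataset.person_ids, columns=dataset.item_ids)
        df.index.name = "person"
        path = out_dir / f"{name}.csv"
        df.to_csv(path)
        paths[name] = path
    if dataset.person_covariates is not None:
        path = out_dir / "person_covariates.csv"
        dataset.person_covariates.to_csv(path)
        paths["person_covariates"] = path
    if dataset.item_covariates is not None:
        path = out_dir / "item_covariates.csv"
        dataset.item_covariates.to_csv(path)
        paths["item_covariates"] = path
    return paths
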