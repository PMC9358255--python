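"""File formats: delimited time courses, HDF5 dFNC containers, configs.

Time courses travel as one delimited text file per subject (rows =
timepoints, columns = components, optional header) listed in a manifest
CSV with ``subject_id`` and ``path`` columns.  dFNC tensors are persisted
in a single HDF5 container with one group per subject, supporting lazy
per-subject loading so the two-step pipeline can honor its partial-loading
contract on disk-backed data.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
import h5py
import numpy as np
import pandas as pd
import yaml

from .exceptions import SchemaError, ValidationError
from .windows import ComponentTimeCourses, DFNCTensor

__all__ = [
    "read_timecourses",
    "write_timecourses",
    "write_dfnc_hdf5",
    "read_dfnc_hdf5",
    "HDF5TensorSource",
    "RunConfig",
]

SCHEMA_VERSION = "dfnckit-tensor-1"


def _read_one_timecourse(subject_id: str, path: Path) -> ComponentTimeCourses:
    try:
        raw = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str)
    except (OSError, pd.errors.ParserError) as exc:
        raise ValidationError(f"{path}: cannot parse ({exc})") from exc

    def _try_float(frame: pd.DataFrame) -> pd.DataFrame | None:
        try:
            return frame.astype(np.float64)
        except (TypeError, ValueError):
            return None

    numeric = _try_float(raw)
    header_offset = 0
    if numeric is None:
        # first row may be a header; retry without it
        numeric = _try_float(raw.iloc[1:])
        header_offset = 1
        if numeric is None:
            body = raw.iloc[1:].reset_index(drop=True)
            for r in range(body.shape[0]):
                for c in range(body.shape[1]):
                    try:
                        float(body.iat[r, c])
                    except (TypeError, ValueError):
                        raise ValidationError(
                            f"{path}: non-numeric value {body.iat[r, c]!r} at "
                            f"row {r + 2}, column {c + 1}"
                        ) from None
            raise ValidationError(f"{path}: could not coerce values to float")
    values = numeric.to_numpy()
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise ValidationError(
            f"{path}: missing or ragged value at row {int(r) + 1 + header_offset}, "
            f"column {int(c) + 1}"
        )
    return ComponentTimeCourses(subject_id=subject_id, data=values)


def read_timecourses(manifest_path: str | Path) -> list[ComponentTimeCourses]:
    """Load all subjects listed in a manifest CSV.

    Relative paths in the manifest are resolved against the manifest's
    own directory.  All subjects must share the same component count.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    for col in ("subject_id", "path"):
        if col not in manifest.columns:
            raise ValidationError(f"manifest is missing the {col!r} column")
    if manifest["subject_id"].duplicated().any():
        raise ValidationError("manifest contains duplicate subject ids")

    out: list[ComponentTimeCourses] = []
    n_components: int | None = None
    for row in manifest.itertuples(index=False):
        path = Path(row.path)
        if not path.is_absolute():
            path = manifest_path.parent / path
        if not path.exists():
            raise ValidationError(f"manifest entry {row.subject_id!r}: {path} not found")
        tc = _read_one_timecourse(str(row.subject_id), path)
        if n_components is None:
            n_components = tc.n_components
        elif tc.n_components != n_components:
            raise ValidationError(
                f"{path}: has {tc.n_components} components, expected "
                f"{n_components} (from the first subject)"
            )
        out.append(tc)
    return out


def write_timecourses(
    out_dir: str | Path,
    timecourses: list[ComponentTimeCourses],
    delimiter: str = "\t",
) -> Path:
    """Write one TSV per subject plus a manifest.csv; returns the manifest
    path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for tc in timecourses:
        fname = f"{tc.subject_id}.tsv"
        np.savetxt(out_dir / fname, tc.data, delimiter=delimiter, fmt="%.17g")
        records.append({"subject_id": tc.subject_id, "path": fname})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame.from_records(records).to_csv(manifest, index=False)
    return manifest


def write_dfnc_hdf5(path: str | Path, tensors: list[DFNCTensor]) -> None:
    """Persist a tensor collection; lossless float64 round trip."""
    if not tensors:
        raise ValidationError("no tensors to write")
    f0 = tensors[0]
    for t in tensors:
        if t.n_features != f0.n_features or not np.array_equal(
            t.feature_index, f0.feature_index
        ):
            raise ValidationError("tensors must share the same feature index")
    with h5py.File(path, "w") as h5:
        h5.attrs["schema_version"] = SCHEMA_VERSION
        h5.create_dataset("feature_index", data=f0.feature_index)
        grp = h5.create_group("subjects")
        for t in tensors:
            sub = grp.create_group(t.subject_id)
            sub.create_dataset("data", data=t.data)
            sub.create_dataset("window_starts", data=t.window_starts)
            sub.attrs["fisher_z"] = bool(t.fisher_z)


def _check_schema(h5: h5py.File, path) -> None:
    version = h5.attrs.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaError(
            f"{path}: schema version {version!r} does not match {SCHEMA_VERSION!r}"
        )
    if "feature_index" not in h5:
        raise SchemaError(f"{path}: missing /feature_index")
    if "subjects" not in h5:
        raise SchemaError(f"{path}: missing /subjects")


class HDF5TensorSource:
    """Lazy, batch-friendly tensor source backed by an HDF5 container.

    Only the requested subject's datasets are materialized on each
    :meth:`get`, so the pipeline's peak residency stays at one batch.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        with h5py.File(self.path, "r") as h5:
            _check_schema(h5, self.path)
            self._subject_ids = list(h5["subjects"].keys())

    @property
    def subject_ids(self) -> list[str]:
        return list(self._subject_ids)

    def get(self, subject_id: str) -> DFNCTensor:
        with h5py.File(self.path, "r") as h5:
            sub = h5["subjects"][subject_id]
            return DFNCTensor(
                subject_id=subject_id,
                data=sub["data"][()],
                window_starts=sub["window_starts"][()],
                feature_index=h5["feature_index"][()],
                fisher_z=bool(sub.attrs.get("fisher_z", False)),
            )


def read_dfnc_hdf5(path: str | Path) -> list[DFNCTensor]:
    """Load an entire container eagerly (convenience for small data)."""
    src = HDF5TensorSource(path)
    return [src.get(sid) for sid in src.subject_ids]


@dataclasses.dataclass
class RunConfig:
    """Serializable snapshot of everything needed to reproduce a run."""

    command: str
    window_length: int = 30
    window_step: int = 1
    taper_sigma: float = 3.0
    method: str = "two-step"
    m: float = 2
    L: int = 6
    k_range: tuple[int, int] = (2, 10)
    elbow_method: str = "curvature"
    metric: str = "sqeuclidean"
    seed: int = 0
    inputs: dict = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_range"] = list(self.k_range)
        return d

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["k_range"] = tuple(d.get("k_range", (2, 10)))
        return cls(**d)


def write_json_report(path: str | Path, payload: dict, kind: str) -> None:
    """Versioned JSON report writer used by the CLI."""
    doc = {"report_kind": kind, "schema_version": 1, **payload}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"cannot serialize {type(obj)!r}")
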