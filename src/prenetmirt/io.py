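"""Reading/writing response matrices, fit outputs and run configurations."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model_core import ResponseMatrix
from .stem import StemConfig

__all__ = ["RunConfig", "read_responses", "write_responses", "write_fit", "write_report"]


@dataclass
class RunConfig:
    """Serializable description of a fitting run (file-based interface).

    ``rho_start``/``rho_factor``/``rho_count`` define the geometric
    grid rho_start * rho_factor^t, t = 0..rho_count-1; the defaults are
    None, which means the penalty's standard grid (3*0.8^t for prenet,
    0.1*0.8^t for l1).
    """

    input: str | None = None
    n_factors: int = 3
    penalty: str = "prenet"
    gamma: float = 0.1
    rho_start: float | None = None
    rho_factor: float = 0.8
    rho_count: int = 21
    n_burnin: int = 300
    n_average: int = 100
    n_burnin_warm: int | None = None
    inner_max_iter: int = 200
    inner_tol: float = 1e-6
    seed: int | None = None
    outdir: str = "."

    def stem_config(self) -> StemConfig:
        return StemConfig(
            n_burnin=self.n_burnin,
            n_average=self.n_average,
            n_burnin_warm=self.n_burnin_warm,
            inner_max_iter=self.inner_max_iter,
            inner_tol=self.inner_tol,
            seed=self.seed,
        )

    def rho_grid(self) -> np.ndarray | None:
        if self.rho_start is None:
            return None
        return self.rho_start * self.rho_factor ** np.arange(self.rho_count)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_responses(path) -> ResponseMatrix:
    """Read a 0/1 response matrix from delimited text (CSV or TSV).

    A non-numeric first row is treated as item IDs and a non-numeric
    first column as subject IDs.  Any cell that is not exactly 0 or 1 is
    reported with its subject row and item column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str)
    except pd.errors.EmptyDataError as err:
        raise ValueError(f"{path}: empty response file") from err
    except Exception as err:
        if path.stat().st_size == 0:
            raise ValueError(f"{path}: empty response file") from err
        # delimiter sniffing fails on single-column files; fall back to comma
        df = pd.read_csv(path, sep=",", header=None, dtype=str)
    if df.empty:
        raise ValueError(f"{path}: empty response file")
    df = df.astype(str).apply(lambda col: col.str.strip())

    def _numeric(x: str) -> bool:
        try:
            float(x)
            return True
        except ValueError:
            return False

    has_header = not df.iloc[0].map(_numeric).all()
    item_ids = df.iloc[0].tolist() if has_header else None
    body = df.iloc[1:] if has_header else df
    first_col = body.iloc[:, 0]
    # first column is subject IDs if non-numeric, or (under a header row)
    # numeric but clearly not response values
    has_index = (not first_col.map(_numeric).all()) or (
        has_header and not set(first_col) <= {"0", "1"}
    )
    subject_ids = first_col.tolist() if has_index else None
    if has_index:
        body = body.iloc[:, 1:]
        if item_ids is not None:
            item_ids = item_ids[1:]
    values = np.empty(body.shape, dtype=np.int8)
    for r in range(body.shape[0]):
        for c in range(body.shape[1]):
            cell = body.iat[r, c]
            if cell not in ("0", "1"):
                sid = subject_ids[r] if subject_ids else r + 1
                iid = item_ids[c] if item_ids else c + 1
                raise ValueError(
                    f"{path}: non-binary value {cell!r} at subject {sid!r}, item {iid!r}"
                )
            values[r, c] = int(cell)
    return ResponseMatrix(values, item_ids=item_ids, subject_ids=subject_ids)


def write_responses(Y: ResponseMatrix, path) -> None:
    Y.to_dataframe().to_csv(path, index=True, index_label="subject")


def write_fit(results, outdir, config: RunConfig | None = None, path_results=None) -> dict:
    """Write loadings, intercepts, path summary and run metadata to a directory.

    ``results`` is a :class:`~prenetmirt.model.MIRTResults`;
    ``path_results`` optionally a :class:`~prenetmirt.model.MIRTPathResults`.
    Returns the mapping of written file paths.  Exact zeros serialize as "0".
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}

    loadings = results.loadings
    fp = outdir / "loadings.csv"
    loadings.to_csv(fp, index_label="item", float_format="%.10g")
    written["loadings"] = str(fp)

    fp = outdir / "intercepts.csv"
    results.intercepts.to_csv(fp, index_label="item", float_format="%.10g")
    written["intercepts"] = str(fp)

    if path_results is not None:
        fp = outdir / "path_summary.csv"
        path_results.frame.to_csv(fp, index=False, float_format="%.10g")
        written["path_summary"] = str(fp)

    meta = {
        "config": (config.to_dict() if config is not None else None),
        "stem_config": dataclasses.asdict(results.config),
        "rho": results.rho,
        "p0": results.p0,
        "loglik": results.loglik,
        "bic": results.bic,
        "n_subjects": results.model.responses.n_subjects,
        "n_items": results.model.responses.n_items,
        "n_factors": results.model.n_factors,
        "penalty": results.model.penalty_kind,
        "gamma": results.model.gamma,
    }
    fp = outdir / "run_metadata.json"
    with open(fp, "w") as fh:
        json.dump(meta, fh, indent=2)
    written["metadata"] = str(fp)
    return written


def write_report(report, outdir) -> str:
    """Write an :class:`~prenetmirt.evaluate.EvalReport` results table as CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fp = outdir / f"experiment_{report.method}_N{report.n_subjects}.csv"
    df = report.results.copy()
    df.insert(0, "method", report.method)
    df.insert(1, "n_subjects", report.n_subjects)
    df.to_csv(fp, index=False)
    return str(fp)
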