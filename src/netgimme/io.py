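"""Reading and writing pipeline inputs and outputs.

Time series travel as headered CSV/TSV (delimiter auto-detected), one
file per subject with the filename stem as subject id; atlases as
two-column roi,network tables; outcomes as a single delimited table.
Result graphs are written per subject as edge-list CSVs plus GraphML.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path as FsPath

import igraph as ig
import numpy as np
import pandas as pd

from .atlas import AtlasError, NetworkAtlas
from .gimme import GimmeResult


class FormatError(ValueError):
    """Input file does not match the expected schema."""


@dataclass(frozen=True)
class ROITimeseries:
    """One subject's T x p matrix, columns in atlas order."""

    subject_id: str
    data: np.ndarray
    tr_seconds: float = 0.72

    def __post_init__(self) -> None:
        X = np.asarray(self.data, dtype=float)
        if np.isnan(X).any():
            raise FormatError(f"{self.subject_id}: missing values in time series")
        p = X.shape[1]
        if X.shape[0] < 2 * p + 1:
            raise FormatError(
                f"{self.subject_id}: need at least {2 * p + 1} time points for {p} ROIs"
            )
        if self.tr_seconds <= 0:
            raise FormatError("tr_seconds must be positive")
        object.__setattr__(self, "data", X)


def _read_delimited(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def read_roi_timeseries(path, atlas: NetworkAtlas, tr_seconds: float = 0.72) -> ROITimeseries:
    """Read one subject's series; columns are checked against the atlas."""
    path = FsPath(path)
    df = _read_delimited(path)
    missing = [r for r in atlas.roi_names if r not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing ROI column(s) {missing}")
    extra = [c for c in df.columns if c not in atlas.roi_names]
    if extra:
        raise FormatError(f"{path.name}: unexpected column(s) {extra}")
    df = df[list(atlas.roi_names)]
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        if bad.isna().any():
            row = int(np.nonzero(bad.isna().to_numpy())[0][0])
            raise FormatError(f"{path.name}: non-numeric value in column {col!r}, row {row}")
    return ROITimeseries(subject_id=path.stem, data=df.to_numpy(float), tr_seconds=tr_seconds)


def write_roi_timeseries(ts: ROITimeseries, path, atlas: NetworkAtlas) -> None:
    pd.DataFrame(ts.data, columns=list(atlas.roi_names)).to_csv(
        path, index=False, float_format="%.15g"
    )


def read_cohort(directory, atlas: NetworkAtlas, tr_seconds: float = 0.72) -> dict[str, np.ndarray]:
    """All CSV/TSV series in a directory, keyed by filename stem."""
    directory = FsPath(directory)
    out = {}
    for path in sorted(directory.glob("*.[ct]sv")):
        ts = read_roi_timeseries(path, atlas, tr_seconds)
        out[ts.subject_id] = ts.data
    if not out:
        raise FormatError(f"no time-series files found in {directory}")
    return out


def read_atlas(path) -> NetworkAtlas:
    """roi,network table -> NetworkAtlas (duplicates and bad labels rejected)."""
    df = _read_delimited(path)
    cols = {c.lower(): c for c in df.columns}
    if "roi" not in cols or "network" not in cols:
        raise FormatError("atlas file needs 'roi' and 'network' columns")
    rois = df[cols["roi"]].astype(str).tolist()
    nets = df[cols["network"]].astype(str).tolist()
    return NetworkAtlas(roi_names=tuple(rois), network_of=dict(zip(rois, nets)))


def write_atlas(atlas: NetworkAtlas, path) -> None:
    pd.DataFrame(
        {"roi": atlas.roi_names, "network": [atlas.network_of[r] for r in atlas.roi_names]}
    ).to_csv(path, index=False)


OUTCOME_NUMERIC = ("slips", "craving_treatment", "cue_craving", "age", "sex", "ftnd", "treatment")


def read_outcomes(path) -> pd.DataFrame:
    """Outcomes/covariates table indexed by subject_id; missingness flagged.

    Missing outcome cells are retained as NaN and surfaced in boolean
    ``missing_<column>`` flags; negative or non-integer slip counts are
    rejected.
    """
    df = _read_delimited(path)
    if "subject_id" not in df.columns:
        raise FormatError("outcomes table needs a 'subject_id' column")
    df = df.set_index("subject_id")
    if df.index.duplicated().any():
        raise FormatError("duplicate subject_id in outcomes table")
    for col in OUTCOME_NUMERIC:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "slips" in df.columns:
        s = df["slips"].dropna()
        if (s < 0).any():
            raise FormatError("slips must be nonnegative")
        if not np.allclose(s, np.round(s)):
            raise FormatError("slips must be integer counts")
    for col in ("slips", "craving_treatment", "cue_craving"):
        if col in df.columns:
            df[f"missing_{col}"] = df[col].isna()
    return df


# ---------------------------------------------------------------------------
# result graphs

EDGE_COLUMNS = ("source", "target", "lag", "estimate", "se", "z", "level")


def _subject_edge_frame(result: GimmeResult, sid: str, atlas: NetworkAtlas) -> pd.DataFrame:
    sub = result.subjects[sid]
    rows = []
    p = sub.pattern.p
    for s, t, lag in sub.pattern.free_paths():
        level = "group" if (lag == 1 and s == t) else sub.levels[(s, t, lag)]
        mat = sub.fit.Phi_hat if lag else sub.fit.A_hat
        se = (sub.fit.se_Phi if lag else sub.fit.se_A)[t, s]
        z = (sub.fit.z_Phi if lag else sub.fit.z_A)[t, s]
        rows.append(
            {
                "source": atlas.roi_names[s],
                "target": atlas.roi_names[t],
                "lag": lag,
                "estimate": mat[t, s],
                "se": se,
                "z": z,
                "level": level,
            }
        )
    return pd.DataFrame(rows, columns=list(EDGE_COLUMNS))


def write_result_graphs(result: GimmeResult, directory, atlas: NetworkAtlas) -> list[str]:
    """Per-subject edge lists (CSV) + GraphML, plus a cohort summary CSV."""
    directory = FsPath(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for sid in result.subject_ids:
        edges = _subject_edge_frame(result, sid, atlas)
        csv_path = directory / f"{sid}_edges.csv"
        edges.to_csv(csv_path, index=False, float_format="%.15g")
        written.append(str(csv_path))

        g = ig.Graph(directed=True)
        g.add_vertices(list(atlas.roi_names))
        g.vs["network"] = [atlas.network_of[r] for r in atlas.roi_names]
        if len(edges):
            g.add_edges(list(zip(edges["source"], edges["target"])))
            for col in ("lag", "estimate", "se", "z", "level"):
                g.es[col] = list(edges[col])
        gml_path = directory / f"{sid}.graphml"
        g.write_graphml(str(gml_path))
        written.append(str(gml_path))

    summary = pd.DataFrame(
        {
            "subject_id": result.subject_ids,
            "subgroup": [result.subgroup_solution.assignment[s] for s in result.subject_ids],
            "n_paths": [result.subjects[s].pattern.n_free for s in result.subject_ids],
            "converged": [result.subjects[s].converged for s in result.subject_ids],
            "CFI": [result.subjects[s].indices.CFI for s in result.subject_ids],
            "NNFI": [result.subjects[s].indices.NNFI for s in result.subject_ids],
            "RMSEA": [result.subjects[s].indices.RMSEA for s in result.subject_ids],
            "SRMR": [result.subjects[s].indices.SRMR for s in result.subject_ids],
        }
    )
    summary_path = directory / "cohort_summary.csv"
    summary.to_csv(summary_path, index=False)
    written.append(str(summary_path))
    return written


def read_edge_list(path, atlas: NetworkAtlas) -> list[tuple[int, int, int, float]]:
    """Edge-list CSV -> (source_idx, target_idx, lag, estimate) tuples."""
    df = pd.read_csv(path)
    return [
        (atlas.index_of(r.source), atlas.index_of(r.target), int(r.lag), float(r.estimate))
        for r in df.itertuples()
    ]
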