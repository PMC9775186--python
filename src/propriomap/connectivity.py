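"""Connectome normalization and anatomy feature assembly.

Directed streamline counts between the eight proprioceptive-network ROIs
(S1, SMG, AG, SPL, SMA, dPMC, vPMC, STG) are seed-volume normalized,
symmetrized by pair averaging, and combined with lesioned-hemisphere
FA/MD for the five association tracts into the 38-column feature table
used by the impairment classifier (10 tract metrics + 28 ROI pairs).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .synthetic import ROI_LABELS, TRACTS

ROI_INDEX = {roi: i for i, roi in enumerate(ROI_LABELS)}


def pair_name(a: str, b: str) -> str:
    """Canonical unordered pair name: endpoints sorted lexically."""
    return "-".join(sorted((a, b)))


def pair_columns() -> list[str]:
    """The 28 unordered ROI pair names in fixed lexical order."""
    return sorted(pair_name(a, b) for a, b in combinations(ROI_LABELS, 2))


def tract_metric_columns() -> list[str]:
    return [f"{m}_{t}" for t in TRACTS for m in ("FA", "MD")]


FEATURE_COLUMNS = tract_metric_columns() + pair_columns()  # 10 + 28 = 38


def normalize_streamlines(
    counts: np.ndarray | pd.DataFrame, seed_volumes: dict[str, float] | np.ndarray
) -> pd.DataFrame:
    """Directed streamline counts -> streamlines per mm^3 of seed.

    value(a -> b) = count(a -> b) / volume(a).  Accepts an 8x8 array/frame
    indexed in ``ROI_LABELS`` order or an edge-list frame with columns
    roi_from, roi_to, streamlines (and optionally seed_volume_mm3).
    """
    if isinstance(counts, pd.DataFrame) and "roi_from" in counts.columns:
        mat = np.zeros((8, 8))
        for row in counts.itertuples(index=False):
            mat[ROI_INDEX[row.roi_from], ROI_INDEX[row.roi_to]] = row.streamlines
        counts = mat
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (8, 8):
        raise ValueError("expected an 8x8 directed count matrix")
    if (counts < 0).any():
        raise ValueError("streamline counts must be non-negative")
    if isinstance(seed_volumes, dict):
        vols = np.array([seed_volumes[r] for r in ROI_LABELS], dtype=float)
    else:
        vols = np.asarray(seed_volumes, dtype=float)
    if (vols <= 0).any():
        raise ValueError("seed volumes must be positive")
    out = counts / vols[:, None]
    return pd.DataFrame(out, index=list(ROI_LABELS), columns=list(ROI_LABELS))


def symmetrize(directed: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Average the two directions per pair; zero the diagonal."""
    if isinstance(directed, pd.DataFrame):
        labels = list(directed.index)
        arr = directed.to_numpy(dtype=float)
    else:
        arr = np.asarray(directed, dtype=float)
        labels = list(ROI_LABELS)[: arr.shape[0]]
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("connectivity matrix must be square")
    sym = (arr + arr.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    return pd.DataFrame(sym, index=labels, columns=labels)


def connectivity_features(sym: pd.DataFrame) -> dict[str, float]:
    """Flatten a symmetric matrix into the 28 named pair values."""
    out = {}
    for a, b in combinations(list(sym.index), 2):
        out[pair_name(a, b)] = float(sym.loc[a, b])
    return out


def assemble_features(
    tract_metrics: pd.DataFrame,
    connectivity: dict[str, pd.DataFrame],
    outcomes: dict[str, bool] | pd.Series,
) -> pd.DataFrame:
    """Build the participants x 38 anatomy feature table with outcome.

    ``tract_metrics`` carries lesioned-hemisphere FA/MD per participant and
    tract (columns participant, tract, FA, MD); ``connectivity`` maps
    participant -> symmetric 8x8 matrix (lesioned hemisphere); ``outcomes``
    maps participant -> impaired flag.  Column order is fixed: FA/MD per
    tract, then the 28 pairs lexically; the flag lands in ``impaired``.
    """
    outcomes = pd.Series(outcomes)
    rows = {}
    metrics = tract_metrics.set_index(["participant", "tract"])
    for pid in outcomes.index:
        row = {}
        for tract in TRACTS:
            try:
                rec = metrics.loc[(pid, tract)]
            except KeyError:
                raise ValueError(f"missing tract metrics for {pid}/{tract}") from None
            row[f"FA_{tract}"] = float(rec["FA"])
            row[f"MD_{tract}"] = float(rec["MD"])
        if pid not in connectivity:
            raise ValueError(f"missing connectivity matrix for {pid}")
        row.update(connectivity_features(connectivity[pid]))
        rows[pid] = row
    table = pd.DataFrame.from_dict(rows, orient="index")[FEATURE_COLUMNS]
    if table.isna().any().any():
        raise ValueError("feature table has missing cells")
    table["impaired"] = outcomes.loc[table.index].astype(bool)
    table.index.name = "participant"
    return table
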