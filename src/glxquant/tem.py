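"""Electron-microscopy morphometry from grid-intersection annotation tables.

Glycocalyx thickness is the Euclidean distance from the luminal phospholipid
point at each grid intersection to the farthest glycocalyx point; a
thickness of at most ``uncovered_max`` (default 10 nm, boundary inclusive)
counts as uncovered, and coverage is the covered percentage of the
intersections.  GBM, foot-process and slit widths are means of annotated
point-pair distances; fenestration and foot-process densities are counts
per micrometre of GBM.  Annotation tables are consumed as CSV; no
micrograph segmentation happens here.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TEMAnnotation",
    "TEMSummary",
    "point_thickness",
    "thicknesses",
    "coverage_percent",
    "width_mean",
    "linear_density",
    "summarize",
    "annotation_to_frame",
    "read_annotations",
    "write_annotations",
]

DEFAULT_UNCOVERED_MAX_NM = 10.0

WIDTH_KINDS = ("gbm", "foot_process", "slit")

ANNOTATION_COLUMNS = [
    "record_type",
    "kind",
    "x0_nm",
    "y0_nm",
    "x1_nm",
    "y1_nm",
    "count",
    "gbm_length_um",
    "capillary_id",
    "glomerulus_id",
    "subject_id",
]


@dataclass(frozen=True)
class TEMAnnotation:
    """Annotation table for one capillary: grid-intersection thickness
    point pairs, width point pairs, counts, and the GBM length analysed."""

    intersections: np.ndarray  # (n, 4): x0, y0, x1, y1 in nm
    width_pairs: pd.DataFrame  # columns kind, x0_nm, y0_nm, x1_nm, y1_nm
    counts: dict
    gbm_length_um: float
    capillary_id: str = "cap1"
    glomerulus_id: str = "glom1"
    subject_id: str = "subj1"
    group: str = "default"


@dataclass(frozen=True)
class TEMSummary:
    capillary_id: str
    glomerulus_id: str
    subject_id: str
    group: str
    mean_thickness_nm: float
    coverage_pct: float
    gbm_width_nm: float
    foot_process_width_nm: float
    slit_width_nm: float
    fenestration_density_per_um: float
    foot_process_density_per_um: float
    n_intersections: int


def point_thickness(luminal_point, glycocalyx_point) -> float:
    """Euclidean distance (nm) between the two annotated points."""
    p = np.asarray(luminal_point, dtype=float)
    q = np.asarray(glycocalyx_point, dtype=float)
    if not (np.isfinite(p).all() and np.isfinite(q).all()):
        raise ValueError("annotation points must be finite")
    return float(np.hypot(*(q - p)))


def thicknesses(annotation: TEMAnnotation) -> np.ndarray:
    pts = np.asarray(annotation.intersections, dtype=float)
    return np.hypot(pts[:, 2] - pts[:, 0], pts[:, 3] - pts[:, 1])


def coverage_percent(values, uncovered_max: float = DEFAULT_UNCOVERED_MAX_NM) -> float:
    """Covered percentage: 100 x count(thickness > uncovered_max) / total.

    A measurement of exactly *uncovered_max* counts as uncovered.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("coverage_percent requires at least one measurement")
    return float(100.0 * np.count_nonzero(v > uncovered_max) / v.size)


def width_mean(width_pairs: pd.DataFrame, kind: str) -> float:
    """Mean Euclidean distance of point pairs of one kind (nm)."""
    sel = width_pairs[width_pairs["kind"] == kind]
    if sel.empty:
        raise ValueError(f"no width pairs of kind {kind!r}")
    return float(
        np.hypot(sel["x1_nm"] - sel["x0_nm"], sel["y1_nm"] - sel["y0_nm"]).mean()
    )


def linear_density(count: float, gbm_length_um: float) -> float:
    """Structures per micrometre of GBM."""
    if gbm_length_um <= 0:
        raise ValueError("gbm_length_um must be > 0")
    return count / gbm_length_um


def summarize(
    annotation: TEMAnnotation, uncovered_max: float = DEFAULT_UNCOVERED_MAX_NM
) -> TEMSummary:
    """All morphometry outputs for one capillary; absent measurement kinds
    yield NaN rather than an error."""
    th = thicknesses(annotation) if len(annotation.intersections) else np.array([])
    mean_th = float(th.mean()) if th.size else float("nan")
    cov = coverage_percent(th, uncovered_max) if th.size else float("nan")

    widths = {}
    for kind in WIDTH_KINDS:
        try:
            widths[kind] = width_mean(annotation.width_pairs, kind)
        except (ValueError, KeyError):
            widths[kind] = float("nan")

    gbm_len = annotation.gbm_length_um
    fen = annotation.counts.get("fenestrations")
    fp = annotation.counts.get("foot_processes")
    fen_density = linear_density(fen, gbm_len) if fen is not None else float("nan")
    fp_density = linear_density(fp, gbm_len) if fp is not None else float("nan")

    return TEMSummary(
        capillary_id=annotation.capillary_id,
        glomerulus_id=annotation.glomerulus_id,
        subject_id=annotation.subject_id,
        group=annotation.group,
        mean_thickness_nm=mean_th,
        coverage_pct=cov,
        gbm_width_nm=widths["gbm"],
        foot_process_width_nm=widths["foot_process"],
        slit_width_nm=widths["slit"],
        fenestration_density_per_um=fen_density,
        foot_process_density_per_um=fp_density,
        n_intersections=int(th.size),
    )


def annotation_to_frame(annotation: TEMAnnotation) -> pd.DataFrame:
    """Flatten one annotation into the long CSV schema."""
    ids = {
        "capillary_id": annotation.capillary_id,
        "glomerulus_id": annotation.glomerulus_id,
        "subject_id": annotation.subject_id,
    }
    rows = []
    for x0, y0, x1, y1 in np.asarray(annotation.intersections, dtype=float):
        rows.append(
            {
                "record_type": "intersection",
                "kind": "glycocalyx",
                "x0_nm": x0,
                "y0_nm": y0,
                "x1_nm": x1,
                "y1_nm": y1,
                "count": np.nan,
                "gbm_length_um": np.nan,
                **ids,
            }
        )
    for _, row in annotation.width_pairs.iterrows():
        rows.append(
            {
                "record_type": "width",
                "kind": row["kind"],
                "x0_nm": row["x0_nm"],
                "y0_nm": row["y0_nm"],
                "x1_nm": row["x1_nm"],
                "y1_nm": row["y1_nm"],
                "count": np.nan,
                "gbm_length_um": np.nan,
                **ids,
            }
        )
    for kind, count in annotation.counts.items():
        rows.append(
            {
                "record_type": "count",
                "kind": kind,
                "x0_nm": np.nan,
                "y0_nm": np.nan,
                "x1_nm": np.nan,
                "y1_nm": np.nan,
                "count": count,
                "gbm_length_um": annotation.gbm_length_um,
                **ids,
            }
        )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def write_annotations(annotations, path) -> None:
    frames = [annotation_to_frame(a) for a in annotations]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_annotations(path, group_map: dict | None = None) -> list[TEMAnnotation]:
    """Parse an annotation CSV into per-capillary annotations.

    Malformed rows are reported with their 1-based file line numbers
    (header = line 1).  *group_map* optionally maps subject_id -> group.
    """
    df = pd.read_csv(path)
    missing = set(ANNOTATION_COLUMNS[:2]) | {
        "capillary_id",
        "glomerulus_id",
        "subject_id",
    }
    missing -= set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: annotation file contains no rows")

    bad_lines = []
    for idx, row in df.iterrows():
        line_no = idx + 2
        rtype = row["record_type"]
        if rtype in ("intersection", "width"):
            coords = [row.get(c) for c in ("x0_nm", "y0_nm", "x1_nm", "y1_nm")]
            if any(pd.isna(c) for c in coords):
                bad_lines.append(line_no)
        elif rtype == "count":
            if pd.isna(row.get("count")) or pd.isna(row.get("gbm_length_um")):
                bad_lines.append(line_no)
        else:
            bad_lines.append(line_no)
    if bad_lines:
        raise ValueError(f"{path}: malformed rows at lines {bad_lines}")

    annotations = []
    keys = ["subject_id", "glomerulus_id", "capillary_id"]
    for (subject, glom, cap), sub in df.groupby(keys, sort=True):
        inter = sub[sub["record_type"] == "intersection"]
        widths = sub[sub["record_type"] == "width"][
            ["kind", "x0_nm", "y0_nm", "x1_nm", "y1_nm"]
        ].reset_index(drop=True)
        counts_rows = sub[sub["record_type"] == "count"]
        counts = {
            str(r["kind"]): float(r["count"]) for _, r in counts_rows.iterrows()
        }
        gbm_len = (
            float(counts_rows["gbm_length_um"].iloc[0])
            if not counts_rows.empty
            else float("nan")
        )
        group = (group_map or {}).get(subject, "default")
        annotations.append(
            TEMAnnotation(
                intersections=inter[["x0_nm", "y0_nm", "x1_nm", "y1_nm"]].to_numpy(
                    dtype=float
                ),
                width_pairs=widths,
                counts=counts,
                gbm_length_um=gbm_len,
                capillary_id=str(cap),
                glomerulus_id=str(glom),
                subject_id=str(subject),
                group=group,
            )
        )
    return annotations
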