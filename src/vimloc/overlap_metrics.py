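"""Volumes, normalized volumes, Dice overlap and cohort summary statistics.

Normalized volume expresses a structure as a percentage of the whole
thalamus of the same hemisphere, which makes volumes comparable across
subjects and hemispheres.  Summary spreads use the sample standard
deviation (n - 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .volume_io import COHORT_COLUMNS, ROIMask, validate_cohort_table

__all__ = [
    "volume_mm3",
    "normalized_volume_pct",
    "dice",
    "vlv_vim_ratio_summary",
    "cohort_report",
    "build_cohort_table",
]


def volume_mm3(mask: ROIMask) -> float:
    """Voxel count times voxel volume."""
    return mask.volume_mm3


def normalized_volume_pct(mask: ROIMask, thalamus: ROIMask) -> float:
    """Structure volume as percent of the thalamic volume."""
    if mask.grid != thalamus.grid:
        raise ValueError("mask and thalamus live on different grids")
    if thalamus.voxel_count == 0:
        raise ValueError("thalamus mask is empty")
    return 100.0 * mask.voxel_count / thalamus.voxel_count


def dice(a: ROIMask, b: ROIMask) -> float:
    """Dice coefficient 2|a∩b| / (|a| + |b|); undefined when both are empty."""
    if a.grid != b.grid:
        raise ValueError("masks live on different grids")
    na, nb = a.voxel_count, b.voxel_count
    if na == 0 and nb == 0:
        raise ValueError("Dice is undefined for two empty masks")
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)


def vlv_vim_ratio_summary(table: pd.DataFrame) -> dict:
    """How many times larger the VLV cluster is than the manual Vim outline.

    Computed from the *normalized* percent columns: mean VLV percent over
    all rows with a VLV value, divided by the mean manual-Vim percent over
    the rows with a manual delineation.  The normalized route is used
    because raw mm3/cm3 entries mix units and rounding; the percent columns
    are the per-thalamus quantities the comparison is about.
    """
    table = validate_cohort_table(table)
    vlv = table["vlv_pct"].dropna()
    vim = table["vim_manual_pct"].dropna()
    if len(vlv) == 0 or len(vim) == 0:
        raise ValueError("no eligible rows for the VLV/Vim ratio")
    ratio = float(vlv.mean() / vim.mean())
    return {"mean_ratio": ratio, "rounded": int(round(ratio))}


_SUMMARY_COLUMNS = [c for c in COHORT_COLUMNS if c not in ("subject_id", "hemisphere")]


def cohort_report(table: pd.DataFrame) -> dict:
    """Per-case rows plus min/max/mean/sd summaries for every volume column.

    Returns ``{"cases": DataFrame, "summary": DataFrame}``; the summary has
    one row per statistic (min, max, mean, sd) with sd the sample standard
    deviation.  An empty cohort yields empty frames with the same columns.
    """
    table = validate_cohort_table(table)
    if len(table) == 0:
        summary = pd.DataFrame(columns=["statistic"] + _SUMMARY_COLUMNS)
        return {"cases": table, "summary": summary}
    stats = {
        "min": table[_SUMMARY_COLUMNS].min(),
        "max": table[_SUMMARY_COLUMNS].max(),
        "mean": table[_SUMMARY_COLUMNS].mean(),
        "sd": table[_SUMMARY_COLUMNS].std(ddof=1),
    }
    summary = pd.DataFrame(stats).T.reset_index(names="statistic")
    return {"cases": table, "summary": summary}


def build_cohort_table(cases: list) -> pd.DataFrame:
    """Assemble a cohort table from per-case masks.

    Each case is a mapping with ``subject_id``, ``hemisphere``,
    ``thalamus`` (ROIMask) and optionally ``vim_manual``, ``vim_multiatlas``
    (ROIMask, mm3 columns) and ``vlv`` (ROIMask, cm3 column); missing masks
    yield missing cells.
    """
    rows = []
    for case in cases:
        thalamus = case["thalamus"]
        row = {"subject_id": case["subject_id"], "hemisphere": case["hemisphere"]}
        for key, mm3_col, pct_col, scale in (
            ("vim_manual", "vim_manual_mm3", "vim_manual_pct", 1.0),
            ("vim_multiatlas", "vim_multiatlas_mm3", "vim_multiatlas_pct", 1.0),
            ("vlv", "vlv_cm3", "vlv_pct", 1e-3),
        ):
            mask = case.get(key)
            if mask is None:
                row[mm3_col] = np.nan
                row[pct_col] = np.nan
            else:
                if mask.grid != thalamus.grid:
                    raise ValueError(
                        f"mixed grids for subject {case['subject_id']} ({case['hemisphere']})"
                    )
                row[mm3_col] = volume_mm3(mask) * scale
                row[pct_col] = normalized_volume_pct(mask, thalamus)
        rows.append(row)
    return validate_cohort_table(pd.DataFrame(rows, columns=COHORT_COLUMNS))
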