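"""Reading and writing TAC tables, fit results and NIfTI images.

TAC tables are UTF-8 TSV with columns ``frame_start_s``, ``frame_end_s``,
``activity_Bq_per_mL`` and, for multi-VOI files, a ``voi`` column.  Sampled
curves export as ``t_s`` / ``activity_Bq_per_mL``.  Fit results and
configurations serialise to JSON with explicit unit strings.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .curves import FrameSchedule, FrameTAC, SampledCurve
from .fitting import FitResult
from .kinetics import (
    NewModelParams,
    OneTissueParams,
    RijzewijkParams,
    TaniguchiParams,
)
from .voi import ImageGeometry, VoiMask

__all__ = [
    "read_tacs",
    "write_tacs",
    "write_curve",
    "read_schedule_json",
    "write_schedule_json",
    "params_to_dict",
    "params_from_dict",
    "fit_result_to_dict",
    "save_fit_result",
    "write_cohort_table",
    "read_cohort_table",
    "write_cohort_summary",
    "load_image",
    "load_masks",
    "save_image",
]

TAC_COLUMNS = ("frame_start_s", "frame_end_s", "activity_Bq_per_mL")

_PARAM_UNITS = {
    "f": "mL/min/mL",
    "f_A": "mL/min/mL",
    "f_P": "mL/min/mL",
    "f_p": "mL/min/mL",
    "k": "/min",
    "E": "unitless",
    "V_B": "unitless",
    "dt1": "s",
    "dt2": "s",
}

_PARAM_CLASSES = {
    "1tcm": OneTissueParams,
    "taniguchi": TaniguchiParams,
    "rijzewijk": RijzewijkParams,
    "new_dual_input": NewModelParams,
}


def read_tacs(path, allow_negative: bool = True) -> dict[str, FrameTAC]:
    """Read a TAC TSV into ``{voi_label: FrameTAC}``.

    Files without a ``voi`` column are read as a single unnamed VOI under
    the label ``"tac"``.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TAC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"TAC file {path} lacks required columns {missing}")
    out: dict[str, FrameTAC] = {}
    groups = df.groupby("voi") if "voi" in df.columns else [("tac", df)]
    for label, sub in groups:
        sub = sub.sort_values("frame_start_s")
        schedule = FrameSchedule(
            sub["frame_start_s"].to_numpy(float), sub["frame_end_s"].to_numpy(float)
        )
        out[str(label)] = FrameTAC(
            schedule,
            sub["activity_Bq_per_mL"].to_numpy(float),
            label=str(label),
            allow_negative=allow_negative,
        )
    return out


def write_tacs(tacs: dict[str, FrameTAC], path) -> None:
    """Write several VOIs' frame TACs into one long-format TSV."""
    rows = []
    for label, tac in tacs.items():
        rows.append(
            pd.DataFrame(
                {
                    "voi": label,
                    "frame_start_s": tac.schedule.frame_start,
                    "frame_end_s": tac.schedule.frame_end,
                    "activity_Bq_per_mL": tac.values,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_curve(curve: SampledCurve, path) -> None:
    pd.DataFrame({"t_s": curve.t, "activity_Bq_per_mL": curve.values}).to_csv(
        path, sep="\t", index=False
    )


def read_schedule_json(path) -> FrameSchedule:
    with open(path) as fh:
        data = json.load(fh)
    return FrameSchedule(
        np.asarray(data["frame_start_s"], float), np.asarray(data["frame_end_s"], float)
    )


def write_schedule_json(schedule: FrameSchedule, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "frame_start_s": schedule.frame_start.tolist(),
                "frame_end_s": schedule.frame_end.tolist(),
            },
            fh,
            indent=2,
        )


def params_to_dict(params) -> dict:
    """Serialise a parameter set with its model id and unit strings."""
    values = dataclasses.asdict(params)
    return {
        "model": params.model_id,
        "params": values,
        "units": {k: _PARAM_UNITS[k] for k in values},
    }


def params_from_dict(data: dict):
    cls = _PARAM_CLASSES[data["model"]]
    return cls(**data["params"])


def fit_result_to_dict(result: FitResult, include_trace: bool = True) -> dict:
    out = {
        "model": result.model,
        **params_to_dict(result.params),
        "sse_Bq2_per_mL2": result.sse,
        "diagnostics": result.diagnostics,
    }
    if result.derived is not None:
        out["derived"] = {
            "f_total_mL_per_min_per_mL": result.derived.f_total,
            "V_T": result.derived.V_T,
            "portal_fraction": result.derived.portal_fraction,
        }
    if result.metrics is not None:
        out["metrics"] = dataclasses.asdict(result.metrics)
    if include_trace:
        out["delay_grid_trace"] = [
            {"delays": delays, "sse": sse, "converged": conv}
            for delays, sse, conv in result.trace
        ]
    return out


def save_fit_result(result: FitResult, path, include_trace: bool = True) -> None:
    with open(path, "w") as fh:
        json.dump(fit_result_to_dict(result, include_trace), fh, indent=2)


def write_cohort_table(table: pd.DataFrame, path) -> None:
    """Write a per-subject-per-model cohort table as TSV."""
    table.to_csv(path, sep="\t", index=False)


def read_cohort_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_cohort_summary(summary: dict, prefix) -> None:
    """Write a :func:`~hepaflow.metrics.cohort_summary` result to disk.

    Produces ``<prefix>_summary.json`` (means, SDs and error medians),
    ``<prefix>_summary.txt`` (human-readable tables) and one
    ``<prefix>_comparisons_<metric>.tsv`` per pairwise model-comparison
    matrix of one-sided Wilcoxon p-values.
    """
    prefix = str(prefix)
    payload = {
        "means": summary["means"].to_dict(),
        "sds": summary["sds"].to_dict(),
        "error_medians": summary["error_medians"].to_dict(),
    }
    with open(f"{prefix}_summary.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    with open(f"{prefix}_summary.txt", "w") as fh:
        fh.write("Parameter means by model\n")
        fh.write(summary["means"].to_string())
        fh.write("\n\nParameter SDs by model\n")
        fh.write(summary["sds"].to_string())
        fh.write("\n\nError-metric medians by model\n")
        fh.write(summary["error_medians"].to_string())
        fh.write("\n")
    for metric, mat in summary["comparisons"].items():
        mat.to_csv(f"{prefix}_comparisons_{metric}.tsv", sep="\t")


def load_image(path) -> tuple[np.ndarray, ImageGeometry]:
    """Load a 3-D or 4-D NIfTI image and its grid geometry."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), ImageGeometry.from_nifti(img)


def load_masks(
    path, label_map: Optional[dict[str, int]] = None
) -> dict[str, VoiMask]:
    """Load VOI masks from a NIfTI label volume.

    ``label_map`` maps VOI names to integer label values; without it the
    volume is treated as one binary mask under the label ``"mask"``.
    """
    data, geometry = load_image(path)
    if data.ndim != 3:
        raise ValueError("mask volume must be 3-D")
    if label_map is None:
        return {"mask": VoiMask(data > 0, geometry, "mask")}
    return {
        name: VoiMask(data == value, geometry, name)
        for name, value in label_map.items()
    }


def save_image(data: np.ndarray, geometry: ImageGeometry, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), geometry.affine), str(path))


def load_label_map(path) -> dict[str, int]:
    with open(path) as fh:
        return {str(k): int(v) for k, v in json.load(fh).items()}
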