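"""Model/results interface for the multi-expert agreement analysis.

:class:`DimensionAgreement` is built from the annotation and frame tables
(generated synthetically or loaded from disk); :meth:`DimensionAgreement.fit`
runs measurement → consensus → deviations → summaries → keypoint-error
decomposition and returns an :class:`AgreementResults` carrying every table,
with :meth:`AgreementResults.summary` for a readable report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import geometry, stats
from .measure import DIMENSIONS, KEYPOINT_NAMES, measurements_table

_ANNOTATION_COLUMNS = {
    "frame_id",
    "rater_id",
    "reading_index",
    "keypoint_name",
    "x_px",
    "y_px",
    "missing",
}
_FRAME_COLUMNS = {
    "frame_id",
    "phase",
    "pixel_spacing_row_mm",
    "pixel_spacing_col_mm",
}


class DimensionAgreement:
    """Agreement of each method (AI, individual experts) with expert consensus.

    Parameters
    ----------
    annotations
        Long table ``frame_id, rater_id, reading_index, keypoint_name, x_px,
        y_px, missing``; the AI's single reading shares the schema.
    frames
        Frame metadata ``frame_id, phase, pixel_spacing_row_mm,
        pixel_spacing_col_mm`` (extra columns are kept and ignored).
    ai_id
        Rater id of the automated method; every other rater id is treated as
        an expert.
    """

    def __init__(
        self,
        annotations: pd.DataFrame,
        frames: pd.DataFrame,
        ai_id: str = "AI",
    ) -> None:
        missing_cols = _ANNOTATION_COLUMNS - set(annotations.columns)
        if missing_cols:
            raise ValueError(f"annotations table lacks columns: {sorted(missing_cols)}")
        missing_cols = _FRAME_COLUMNS - set(frames.columns)
        if missing_cols:
            raise ValueError(f"frames table lacks columns: {sorted(missing_cols)}")
        orphans = sorted(set(annotations["frame_id"]) - set(frames["frame_id"]))
        if orphans:
            raise ValueError(
                f"annotations reference frames absent from metadata: {orphans}"
            )
        bad_kp = sorted(set(annotations["keypoint_name"]) - set(KEYPOINT_NAMES))
        if bad_kp:
            raise ValueError(f"unknown keypoint names: {bad_kp}")
        self.annotations = annotations.reset_index(drop=True)
        self.frames = frames.reset_index(drop=True)
        self.ai_id = ai_id
        self.expert_ids: list[str] = sorted(
            set(annotations["rater_id"]) - {ai_id}
        )

    @classmethod
    def from_csv(
        cls,
        annotations_path: str | Path,
        frames_path: str | Path,
        ai_id: str = "AI",
    ) -> "DimensionAgreement":
        return cls(
            annotations=pd.read_csv(annotations_path),
            frames=pd.read_csv(frames_path),
            ai_id=ai_id,
        )

    def fit(
        self,
        *,
        min_experts: int = stats.DEFAULT_MIN_EXPERTS,
        leave_one_out: bool = False,
        consensus: str = "per-expert-median",
        alpha: float = 0.05,
        decomposition_reference: pd.DataFrame | None = None,
    ) -> "AgreementResults":
        """Run the full analysis.

        ``consensus`` selects the reference rule (``"per-expert-median"`` or
        ``"pooled"``); ``leave_one_out`` scores each expert against a
        consensus excluding their own readings (sensitivity analysis — the
        study design keeps them in).  ``decomposition_reference`` optionally
        replaces the consensus keypoints with an explicit reference (e.g.
        synthetic ground truth) for the error decomposition.
        """
        measurements = measurements_table(self.annotations, self.frames)
        reference = stats.consensus_table(
            measurements, self.expert_ids, min_experts=min_experts, method=consensus
        )
        loo = (
            stats.leave_one_out_consensus(
                measurements, self.expert_ids, min_experts=min_experts
            )
            if leave_one_out
            else None
        )
        methods = stats.method_measurements_long(
            measurements, self.expert_ids, ai_id=self.ai_id
        )
        deviations, n_excluded = stats.signed_deviations(
            methods, reference, loo_reference=loo
        )
        summaries = stats.stratified_summaries(deviations)
        tests = stats.comparison_tests(deviations, ai_id=self.ai_id, alpha=alpha)
        decomposition = geometry.decompose_table(
            self.annotations,
            self.frames,
            self.expert_ids,
            ai_id=self.ai_id,
            min_experts=min_experts,
            reference=decomposition_reference,
        )
        decomp_summary, decomp_tests = geometry.decomposition_summary(
            decomposition, ai_id=self.ai_id, alpha=alpha
        )
        return AgreementResults(
            model=self,
            measurements=measurements,
            reference=reference,
            deviations=deviations,
            summaries=summaries,
            tests=tests,
            decomposition=decomposition,
            decomposition_summaries=decomp_summary,
            decomposition_tests=decomp_tests,
            n_excluded=n_excluded,
            options={
                "min_experts": min_experts,
                "leave_one_out": leave_one_out,
                "consensus": consensus,
                "alpha": alpha,
                "icc_form": "ICC(2,1) two-way random, absolute agreement, single rater",
            },
        )


@dataclass
class AgreementResults:
    """All tables produced by one agreement analysis."""

    model: DimensionAgreement
    measurements: pd.DataFrame
    reference: pd.DataFrame
    deviations: pd.DataFrame
    summaries: pd.DataFrame
    tests: pd.DataFrame
    decomposition: pd.DataFrame
    decomposition_summaries: pd.DataFrame
    decomposition_tests: pd.DataFrame
    n_excluded: int
    options: dict = field(default_factory=dict)

    def method_summary(self, method_id: str, dimension: str, phase: str = "pooled") -> pd.Series:
        s = self.summaries
        sel = s[
            (s["method_id"] == method_id)
            & (s["dimension"] == dimension)
            & (s["phase"] == phase)
        ]
        if sel.empty:
            raise KeyError((method_id, dimension, phase))
        return sel.iloc[0]

    def cumulative_error_curve(
        self, method_id: str, dimension: str, phase: str | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        d = self.deviations
        sel = d[(d["method_id"] == method_id) & (d["dimension"] == dimension)]
        if phase is not None:
            sel = sel[sel["phase"] == phase]
        return stats.cumulative_error_curve(sel["signed_deviation_mm"].to_numpy())

    def plot_cumulative_error(self, dimension: str = "lvid", phase: str | None = "ED", ax=None):
        """Cumulative |deviation| curves: each expert in grey, the AI in red."""
        from .plotting import plot_cumulative_error

        return plot_cumulative_error(self, dimension=dimension, phase=phase, ax=ax)

    def summary(self) -> str:
        """Human-readable report of the pooled-phase agreement statistics."""
        lines = [
            "Agreement with expert consensus "
            f"({self.options.get('consensus')} reference, "
            f"min_experts={self.options.get('min_experts')}, "
            f"{'leave-one-out' if self.options.get('leave_one_out') else 'self-inclusive'})",
            f"ICC form: {self.options.get('icc_form')}",
            f"Methods: {len(self.model.expert_ids)} experts + {self.model.ai_id}; "
            f"excluded incomplete rows: {self.n_excluded}",
            "",
        ]
        s = self.summaries
        for dimension in DIMENSIONS:
            lines.append(f"[{dimension}]  (mm)")
            view = s[(s["dimension"] == dimension) & (s["phase"] == "pooled")]
            experts = view[view["method_id"] != self.model.ai_id]
            ai = view[view["method_id"] == self.model.ai_id]
            sub = pd.concat([ai, experts])
            cols = [
                "method_id",
                "n",
                "bias_mm",
                "precision_sd_mm",
                "abs_q50_mm",
                "abs_q80_mm",
                "abs_q95_mm",
                "icc",
            ]
            lines.append(sub[cols].to_string(index=False, float_format=lambda v: f"{v:7.3f}"))
            lines.append("")
        if not self.tests.empty:
            lines.append("Comparisons:")
            lines.append(
                self.tests.to_string(index=False, float_format=lambda v: f"{v:9.4g}")
            )
        return "\n".join(lines)

    def save(self, out_dir: str | Path, float_format: str = "%.6f") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.measurements.to_csv(out / "measurements.csv", index=False, float_format=float_format)
        self.summaries.to_csv(out / "agreement_summary.csv", index=False, float_format=float_format)
        self.tests.to_csv(out / "tests.csv", index=False, float_format=float_format)
        self.decomposition.to_csv(out / "decomposition.csv", index=False, float_format=float_format)
        self.decomposition_summaries.to_csv(
            out / "decomposition_summary.csv", index=False, float_format=float_format
        )
        self.decomposition_tests.to_csv(
            out / "decomposition_tests.csv", index=False, float_format=float_format
        )
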