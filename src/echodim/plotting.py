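"""Plot helpers for agreement results (matplotlib)."""

from __future__ import annotations


def plot_cumulative_error(results, dimension: str = "lvid", phase: str | None = "ED", ax=None):
    """Cumulative absolute-deviation curves: experts grey, AI red.

    Each curve shows, for one method, the fraction of frames (x) whose
    absolute deviation from consensus is below a given magnitude (y, mm).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ai_id = results.model.ai_id
    for rid in results.model.expert_ids:
        fracs, errs = results.cumulative_error_curve(rid, dimension, phase)
        ax.plot(fracs * 100, errs, color="0.6", lw=0.8)
    fracs, errs = results.cumulative_error_curve(ai_id, dimension, phase)
    ax.plot(fracs * 100, errs, color="crimson", lw=2.0, label=ai_id)
    ax.set_xlabel("cumulative fraction of frames (%)")
    ax.set_ylabel(f"|deviation| from consensus (mm), {dimension}" + (f" {phase}" if phase else ""))
    ax.legend()
    return ax


def plot_decomposition(results, method_id: str = "AI", line: str = "lvid", phase: str | None = None, ax=None):
    """Scatter of longitudinal vs transverse error fractions for one method."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    d = results.decomposition
    sel = d[(d["method_id"] == method_id) & (d["line"] == line)]
    if phase is not None:
        sel = sel[sel["phase"] == phase]
    ax.scatter(sel["longitudinal_frac"], sel["transverse_frac"], s=8, alpha=0.6)
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.set_xlabel("longitudinal error (fraction of line)")
    ax.set_ylabel("transverse error (fraction of line)")
    ax.set_title(f"{method_id}, {line}")
    ax.set_aspect("equal")
    return ax
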