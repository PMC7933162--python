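"""Per-ROI time-course plots with significance bars.

One panel per ROI: mean percent-change high-gamma traces per sentence
type with a shaded standard-error band; horizontal bars above the traces
mark significant augmentation epochs and bars below mark suppression.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

_COLORS = {"concrete_first": "tab:red", "wh_first": "tab:blue", "both": "k"}


def plot_roi_timecourse(timecourses, significance=None, *,
                        out_path: str | Path | None = None,
                        title: str | None = None):
    """Plot one ROI's time courses (one line per sentence type).

    ``timecourses`` is a list of :class:`~hgmod.epoching.ROITimeCourse`
    sharing roi/hemisphere/anchor; ``significance`` an optional matching
    list of :class:`~hgmod.pointwise.SignificanceResult`.
    """
    fig, ax = plt.subplots(figsize=(6, 3.5))
    top = max(float(max(tc.mean + tc.se)) for tc in timecourses)
    bot = min(float(min(tc.mean - tc.se)) for tc in timecourses)
    span = max(top - bot, 1.0)

    sig_by_type = {}
    if significance:
        sig_by_type = {r.sentence_type: r for r in significance}

    for k, tc in enumerate(timecourses):
        color = _COLORS.get(tc.sentence_type, f"C{k}")
        ax.plot(tc.times, tc.mean, color=color,
                label=f"{tc.sentence_type} (n={tc.n_electrodes})")
        ax.fill_between(tc.times, tc.mean - tc.se, tc.mean + tc.se,
                        color=color, alpha=0.25, linewidth=0)
        sig = sig_by_type.get(tc.sentence_type)
        if sig is None:
            continue
        for ep in sig.epochs:
            if ep.sign == "augmentation":
                y = top + span * (0.06 + 0.05 * k)
            else:
                y = bot - span * (0.06 + 0.05 * k)
            ax.hlines(y, ep.start_ms, ep.end_ms, color=color, linewidth=3)

    ax.axhline(0.0, color="0.6", linewidth=0.8)
    ax.axvline(0.0, color="0.6", linewidth=0.8, linestyle="--")
    tc0 = timecourses[0]
    ax.set_xlabel(f"time from {tc0.anchor} (ms)")
    ax.set_ylabel("high-gamma change (%)")
    ax.set_title(title or f"{tc0.hemisphere} {tc0.roi}")
    ax.legend(fontsize=8, frameon=False)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
        return None
    return fig
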