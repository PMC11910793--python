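"""Optional matplotlib views of panels and projections."""

from __future__ import annotations

import matplotlib.pyplot as plt

from .panel import WaitlistPanel
from .projection import CounterfactualTrend, ProjectionResult


def plot_panel(panel: WaitlistPanel, ax=None):
    """Pending stock and the two flows over the observation window."""
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4.5))
    for measure, style in (("pending", "-"), ("additions", "--"), ("removals", ":")):
        s = panel.series(measure)
        ax.plot(s.index.to_timestamp(how="end"), s.to_numpy(), style, label=measure)
    ax.set_ylabel("referrals per quarter / on list")
    ax.legend()
    return ax


def plot_projection(
    result: ProjectionResult,
    ax=None,
    counterfactual: CounterfactualTrend | None = None,
):
    """Median projection with its 95% prediction band."""
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4.5))
    x = range(len(result.quarters))
    ax.plot(x, result.p50, label=f"median (X={result.scenario.capacity_increase:.0%})")
    ax.fill_between(x, result.p2_5, result.p97_5, alpha=0.25, label="95% PI")
    if result.scenario.reference_level is not None:
        ax.axhline(result.scenario.reference_level, ls="--", c="grey",
                   label="pre-pandemic reference")
    if counterfactual is not None:
        tail = counterfactual.trajectory.iloc[-len(result.quarters):]
        ax.plot(x, tail.to_numpy(), ls=":", c="k", label="linear counterfactual")
    ax.set_xlabel("projection quarter")
    ax.set_ylabel("pending referrals")
    ax.legend()
    return ax
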