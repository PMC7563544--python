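"""Per-participant aggregation and cross-participant consistency summary.

Each participant's metrics are reduced to medians keyed by movement segment
(forward-deliberate vs. backward-spontaneous) and body side (performing vs.
non-performing), plus the marginal cells pooling the other factor.  Deltas
(forward - backward; performing - non-performing, also conditionally within
each level of the other factor) express the direction of each effect for
that participant.

Across participants, each metric x contrast receives a consistency symbol:
``o`` when the delta has the same sign for every participant, the triangle
(rendered ``Δ``) when the same sign holds for more than half but not all,
and ``-`` otherwise.  The heart lead/lag is summarized per cell as which
signal leads (EKG when the median lag is positive, LS — linear speed —
when negative).  No null-hypothesis significance testing is performed; an
optional sign-test utility is provided but not used by the summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

__all__ = [
    "IntentComparison",
    "ConsistencySummary",
    "assign_sides",
    "aggregate",
    "summarize",
    "format_summary",
    "sign_test",
]

SEGMENTS = ("forward", "backward")
SIDES = ("performing", "non_performing")
METRICS = ("nsr_aa", "nsr_aa_diff", "xcorr", "cc", "emd", "heart_xcorr", "heart_lag")

#: contrasts evaluated for every metric
CONTRASTS = ("forward_minus_backward", "performing_minus_non_performing")
#: additional conditional contrasts (used for the EMD cells of the summary)
CONDITIONAL_CONTRASTS = (
    "fb_within_performing",
    "fb_within_non_performing",
    "pnp_within_forward",
    "pnp_within_backward",
)


def assign_sides(body_part_labels: list[str], handedness: str) -> dict[str, str]:
    """Map sensor labels to performing / non_performing / midline.

    The dominant-side scapula, upper arm, forearm and hand-or-finger are
    performing; the mirror set is non-performing; forehead and T7 are
    midline and excluded from side contrasts.
    """
    if handedness not in ("left", "right"):
        raise ConfigError(f"unknown handedness {handedness!r}")
    out = {}
    for label in body_part_labels:
        if label.startswith(f"{handedness}_"):
            out[label] = "performing"
        elif label.startswith("left_") or label.startswith("right_"):
            out[label] = "non_performing"
        else:
            out[label] = "midline"
    return out


@dataclass
class IntentComparison:
    """One participant's median metrics by segment and side, with deltas."""

    participant: str
    cells: dict[str, dict[tuple[str, str], float]]
    deltas: dict[str, dict[str, float]]
    counts: dict[str, int] = field(default_factory=dict)
    n_participants: int = 1


@dataclass
class ConsistencySummary:
    """Cross-participant consistency symbols per metric and contrast.

    ``symbols[(metric, contrast)] = (symbol, favored)`` where symbol is one
    of ``o``, ``Δ``, ``-`` and favored names the higher category (empty when
    no consistent direction).  ``lead[cell] = (leader, symbol)`` reports
    which signal leads the heart-kinematics pair in each marginal cell.
    """

    symbols: dict[tuple[str, str], tuple[str, str]]
    lead: dict[str, tuple[str, str]]
    n_participants: int
    deltas: dict[tuple[str, str], list[float]] = field(default_factory=dict)


def _median(values: list[float]) -> float:
    vals = [v for v in values if v is not None and np.isfinite(v)]
    return float(np.median(vals)) if vals else float("nan")


def _cells_from_values(
    values: dict[tuple[str, str], list[float]]
) -> dict[tuple[str, str], float]:
    """Cross cells plus marginals from per-(segment, side) value pools.

    Marginal cells are balanced: the unweighted mean of the cross-cell
    medians over the pooled factor.  (The median of a pooled bimodal set is
    an unstable order statistic — it jumps with single-value perturbations
    near the pool's center — whereas balanced marginalization keeps each
    cell's weight fixed.)
    """
    cells: dict[tuple[str, str], float] = {}
    for seg in SEGMENTS:
        for side in values_sides(values):
            cells[(seg, side)] = _median(values.get((seg, side), []))
    for seg in SEGMENTS:
        sub = [cells[(seg, sd)] for sd in values_sides(values)
               if np.isfinite(cells.get((seg, sd), np.nan))]
        cells[(seg, "all")] = float(np.mean(sub)) if sub else float("nan")
    for side in SIDES:
        sub = [cells[(seg, side)] for seg in SEGMENTS
               if np.isfinite(cells.get((seg, side), np.nan))]
        cells[("all", side)] = float(np.mean(sub)) if sub else float("nan")
    return cells


def values_sides(values: dict[tuple[str, str], list[float]]) -> list[str]:
    return sorted({side for (_, side) in values})


def _deltas_from_cells(cells: dict[tuple[str, str], float]) -> dict[str, float]:
    d = {
        "forward_minus_backward": cells[("forward", "all")] - cells[("backward", "all")],
        "performing_minus_non_performing": cells[("all", "performing")]
        - cells[("all", "non_performing")],
    }
    for side in SIDES:
        key = f"fb_within_{side}"
        d[key] = cells.get(("forward", side), np.nan) - cells.get(("backward", side), np.nan)
    for seg in SEGMENTS:
        d[f"pnp_within_{seg}"] = cells.get((seg, "performing"), np.nan) - cells.get(
            (seg, "non_performing"), np.nan
        )
    return d


def aggregate(
    metric_values: dict[str, dict[tuple[str, str], list[float]]],
    participant: str = "p0",
    counts: dict[str, int] | None = None,
) -> IntentComparison:
    """Reduce per-(segment, side) value pools to cells and deltas.

    ``metric_values[metric][(segment, side)]`` holds the per-node (or
    per-pair, per-edge) values entering that cell's median; pools may also
    use side ``"midline"``, which enters segment marginals but no side
    contrast.  Missing cells yield NaN deltas rather than zeros.
    """
    cells, deltas = {}, {}
    for metric, values in metric_values.items():
        c = _cells_from_values(values)
        cells[metric] = c
        deltas[metric] = _deltas_from_cells(c)
    return IntentComparison(participant, cells, deltas, counts or {})


def _symbol(signs: list[int]) -> tuple[str, int]:
    n = len(signs)
    pos = sum(1 for s in signs if s > 0)
    neg = sum(1 for s in signs if s < 0)
    if n == 0:
        return "-", 0
    if pos == n:
        return "o", 1
    if neg == n:
        return "o", -1
    if pos > n / 2:
        return "Δ", 1
    if neg > n / 2:
        return "Δ", -1
    return "-", 0


_FAVORED = {
    "forward_minus_backward": ("forward", "backward"),
    "performing_minus_non_performing": ("performing", "non_performing"),
    "fb_within_performing": ("forward", "backward"),
    "fb_within_non_performing": ("forward", "backward"),
    "pnp_within_forward": ("performing", "non_performing"),
    "pnp_within_backward": ("performing", "non_performing"),
}


def summarize(comparisons: list[IntentComparison]) -> ConsistencySummary:
    """Cross-participant consistency symbols; needs >= 2 participants.

    Symbols are derived purely from the per-participant delta signs and are
    invariant to participant ordering.  EMD additionally receives the
    conditional contrasts (within each segment and within each side).  The
    lead cells report which signal leads (positive median lag = EKG leads
    the kinematics) per marginal cell.
    """
    if len(comparisons) < 2:
        raise ValueError("need >= 2 participants to summarize consistency")
    symbols: dict[tuple[str, str], tuple[str, str]] = {}
    all_deltas: dict[tuple[str, str], list[float]] = {}
    for metric in METRICS:
        contrasts = CONTRASTS + (CONDITIONAL_CONTRASTS if metric == "emd" else ())
        for contrast in contrasts:
            deltas = [c.deltas.get(metric, {}).get(contrast, np.nan) for c in comparisons]
            deltas = [d for d in deltas if np.isfinite(d)]
            sym, direction = _symbol([int(np.sign(d)) for d in deltas])
            hi, lo = _FAVORED[contrast]
            favored = hi if direction > 0 else (lo if direction < 0 else "")
            symbols[(metric, contrast)] = (sym, favored)
            all_deltas[(metric, contrast)] = deltas

    lead: dict[str, tuple[str, str]] = {}
    for cell_name, key in (
        ("forward", ("forward", "all")),
        ("backward", ("backward", "all")),
        ("performing", ("all", "performing")),
        ("non_performing", ("all", "non_performing")),
    ):
        lags = [c.cells.get("heart_lag", {}).get(key, np.nan) for c in comparisons]
        lags = [v for v in lags if np.isfinite(v)]
        sym, direction = _symbol([int(np.sign(v)) for v in lags])
        leader = "EKG" if direction > 0 else ("LS" if direction < 0 else "-")
        lead[cell_name] = (leader, sym)
    return ConsistencySummary(symbols, lead, len(comparisons), all_deltas)


def format_summary(summary: ConsistencySummary) -> str:
    """Plain-text grid in the style of a connectivity summary table."""
    rows = []
    head = f"{'metric':<14}{'Forward':<12}{'Backward':<12}{'Performing':<12}{'Non-Perf':<12}"
    rows.append("Kinematics (AA) network")
    rows.append(head)

    def cell(metric: str, contrast: str, category: str) -> str:
        sym, fav = summary.symbols.get((metric, contrast), ("-", ""))
        return sym if fav == category else ""

    for metric in ("nsr_aa", "nsr_aa_diff", "xcorr", "cc"):
        rows.append(
            f"{metric:<14}"
            f"{cell(metric, 'forward_minus_backward', 'forward'):<12}"
            f"{cell(metric, 'forward_minus_backward', 'backward'):<12}"
            f"{cell(metric, 'performing_minus_non_performing', 'performing'):<12}"
            f"{cell(metric, 'performing_minus_non_performing', 'non_performing'):<12}"
        )
    rows.append("Kinematics (LS)-heart network")
    for metric in ("emd", "heart_xcorr"):
        rows.append(
            f"{metric:<14}"
            f"{cell(metric, 'forward_minus_backward', 'forward'):<12}"
            f"{cell(metric, 'forward_minus_backward', 'backward'):<12}"
            f"{cell(metric, 'performing_minus_non_performing', 'performing'):<12}"
            f"{cell(metric, 'performing_minus_non_performing', 'non_performing'):<12}"
        )
    lead_cells = [summary.lead.get(c, ("-", "-")) for c in
                  ("forward", "backward", "performing", "non_performing")]
    rows.append(
        f"{'lead':<14}" + "".join(f"{leader + ' (' + sym + ')':<12}" for leader, sym in lead_cells)
    )
    return "\n".join(rows)


def sign_test(deltas: list[float]) -> float:
    """Two-sided sign-test p-value on delta signs (optional utility)."""
    from scipy import stats

    pos = sum(1 for d in deltas if d > 0)
    n = sum(1 for d in deltas if d != 0)
    if n == 0:
        return 1.0
    return float(stats.binomtest(pos, n, 0.5).pvalue)
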