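"""Thresholding, degree-of-agreement scoring and group statistics.

A likelihood threshold ``alpha`` turns the per-electrode weights into the
algorithm's predicted epileptogenic-zone set (AEZ).  Agreement with the
clinically annotated set (CEZ) is the degree of agreement

    DOA = |CEZ n AEZ| / |CEZ|  -  |~CEZ n AEZ| / |~CEZ|,

i.e. sensitivity minus false-positive rate, in [-1, 1]: 1 is perfect
agreement, -1 perfect disagreement, and an empty AEZ scores 0 (no
prediction — possibly no electrode coverage of the EZ).

Group statistics compare the DOA distributions of successful versus
failed surgical outcomes with the two-sided Wilcoxon rank-sum test, per
center and pooled, with an additional per-center min-max scaling so
centers can be compared on a common [0, 1] scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .exceptions import ScoringError

#: Combined sample size up to which the exact rank-sum null is used.
_EXACT_N = 20


def threshold_to_aez(likelihoods: Mapping[str, float],
                     alpha: float) -> frozenset[str]:
    """Channels whose likelihood strictly exceeds ``alpha``.

    May be empty ("no visible EZ"), which downstream scoring treats as a
    neutral prediction.
    """
    if not 0 <= alpha < 1:
        raise ScoringError(f"alpha must be in [0, 1), got {alpha}")
    return frozenset(c for c, v in likelihoods.items() if v > alpha)


def degree_of_agreement(cez: Iterable[str], aez: Iterable[str],
                        all_channels: Iterable[str]) -> float:
    """Degree of agreement between predicted and clinical electrode sets."""
    cez = frozenset(cez)
    aez = frozenset(aez)
    channels = frozenset(all_channels)
    if not cez:
        raise ScoringError("CEZ is empty; agreement undefined")
    if not cez < channels:
        raise ScoringError(
            "CEZ must be a proper subset of all channels; "
            "the complement denominator is undefined otherwise"
        )
    if not aez <= channels:
        raise ScoringError("AEZ contains unknown channels")
    complement = channels - cez
    return len(cez & aez) / len(cez) - len(complement & aez) / len(complement)


@dataclass
class LocalizationResult:
    """Scored localization of one seizure event."""

    likelihoods: dict[str, float]
    alpha: float
    aez: frozenset[str]
    cez: frozenset[str]
    doa: float
    seizure_id: str = ""
    patient_id: str = ""
    center_id: str = ""
    outcome: str | None = None

    @property
    def no_visible_ez(self) -> bool:
        """True when no electrode exceeded the threshold."""
        return len(self.aez) == 0


def score_localization(likelihoods: Mapping[str, float], alpha: float,
                       cez: Iterable[str], *, seizure_id: str = "",
                       patient_id: str = "", center_id: str = "",
                       outcome: str | None = None) -> LocalizationResult:
    """Threshold likelihoods and score agreement in one step."""
    aez = threshold_to_aez(likelihoods, alpha)
    doa = degree_of_agreement(cez, aez, likelihoods.keys())
    return LocalizationResult(
        likelihoods=dict(likelihoods), alpha=alpha, aez=aez,
        cez=frozenset(cez), doa=doa, seizure_id=seizure_id,
        patient_id=patient_id, center_id=center_id, outcome=outcome,
    )


def minmax_scale_by_center(
    doas: Mapping[str, Sequence[float]],
) -> dict[str, list[float]]:
    """Min-max scale agreement values within each center to [0, 1].

    A center whose values are all equal maps to 0 (degenerate case).
    """
    scaled: dict[str, list[float]] = {}
    for center, values in doas.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size == 0:
            raise ScoringError(f"center {center!r} has no values")
        lo, hi = arr.min(), arr.max()
        if hi == lo:
            scaled[center] = [0.0] * arr.size
        else:
            scaled[center] = ((arr - lo) / (hi - lo)).tolist()
    return scaled


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Uses the exact null distribution when the combined sample is small
    (n <= 20) and tie-free, and the tie-corrected,
    continuity-corrected normal approximation otherwise.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ScoringError("both groups must be nonempty")
    no_ties = np.unique(np.concatenate([x, y])).size == x.size + y.size
    method = "exact" if (x.size + y.size <= _EXACT_N and no_ties) \
        else "asymptotic"
    return float(stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method
    ).pvalue)


def _group_stats(success: Sequence[float],
                 failure: Sequence[float]) -> dict:
    success = np.asarray(list(success), dtype=float)
    failure = np.asarray(list(failure), dtype=float)
    entry: dict = {
        "n_success": int(success.size),
        "n_failure": int(failure.size),
        "success_mean": float(success.mean()) if success.size else None,
        "success_sd": float(success.std(ddof=1)) if success.size > 1 else None,
        "failure_mean": float(failure.mean()) if failure.size else None,
        "failure_sd": float(failure.std(ddof=1)) if failure.size > 1 else None,
    }
    if success.size >= 2 and failure.size >= 2:
        entry["p_value"] = rank_sum_test(success, failure)
        entry["incomputable"] = False
    else:
        entry["p_value"] = None
        entry["incomputable"] = True
    return entry


def group_comparison(results: Sequence[LocalizationResult]) -> dict:
    """Success-versus-failure agreement report, per center and pooled.

    Returns a dict with ``raw`` and ``scaled`` (per-center min-max
    normalized) sections, each holding per-center entries and a pooled
    ``all`` entry with group means, SDs and the rank-sum p-value.
    """
    scored = [r for r in results if r.outcome in ("success", "failure")]
    if not scored:
        raise ScoringError("no results carry an outcome label")
    centers = sorted({r.center_id for r in scored})

    def collect(values_by_result: Mapping[int, float]) -> dict:
        sections: dict = {"per_center": {}}
        for center in centers:
            s = [values_by_result[i] for i, r in enumerate(scored)
                 if r.center_id == center and r.outcome == "success"]
            f = [values_by_result[i] for i, r in enumerate(scored)
                 if r.center_id == center and r.outcome == "failure"]
            sections["per_center"][center] = _group_stats(s, f)
        s = [values_by_result[i] for i, r in enumerate(scored)
             if r.outcome == "success"]
        f = [values_by_result[i] for i, r in enumerate(scored)
             if r.outcome == "failure"]
        sections["all"] = _group_stats(s, f)
        return sections

    raw = {i: r.doa for i, r in enumerate(scored)}
    by_center: dict[str, list[int]] = {c: [] for c in centers}
    for i, r in enumerate(scored):
        by_center[r.center_id].append(i)
    scaled_lists = minmax_scale_by_center(
        {c: [scored[i].doa for i in idx] for c, idx in by_center.items()}
    )
    scaled = {
        i: v
        for c, idx in by_center.items()
        for i, v in zip(idx, scaled_lists[c])
    }
    return {
        "alpha": scored[0].alpha,
        "n_results": len(scored),
        "raw": collect(raw),
        "scaled": collect(scaled),
    }


def report_markdown(report: dict) -> str:
    """Render a group-comparison report as a Markdown table."""

    def fmt(entry: dict) -> str:
        def ms(mean, sd):
            if mean is None:
                return "--"
            return f"{mean:.2f} ± {sd:.2f}" if sd is not None else f"{mean:.2f}"

        p = entry["p_value"]
        ptxt = f"{p:.4g}" if p is not None else "--"
        return (f"{ms(entry['success_mean'], entry['success_sd'])} | "
                f"{ms(entry['failure_mean'], entry['failure_sd'])} | {ptxt}")

    lines = [
        f"Degree of agreement at alpha = {report['alpha']}",
        "",
        "| Center | DOA success | DOA failure | p value |",
        "|---|---|---|---|",
    ]
    for section, tag in (("raw", ""), ("scaled", " (min-max scaled)")):
        for center, entry in report[section]["per_center"].items():
            lines.append(f"| {center}{tag} | {fmt(entry)} |")
        lines.append(f"| All{tag} | {fmt(report[section]['all'])} |")
    return "\n".join(lines) + "\n"
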