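"""Polymorph risk statistics from an assembled energy landscape.

Three textbook relations drive the assessment:

* **Stability probability.**  Treating the computed pairwise free-energy
  difference ΔF (challenger − reference, positive = challenger less stable)
  as Gaussian with standard error σ, the probability that the challenger is
  actually the more stable form is the one-sided tail Φ(−ΔF/σ).  σ is the
  free-energy model's one standard error applied directly to the pairwise
  difference.

* **Solubility ratio.**  Two polymorphs in equilibrium with the same
  solution satisfy S_ref/S_new = exp(ΔF/RT): a candidate ΔF kJ/mol below
  the reference form implies an exp(ΔF/RT)-fold solubility loss if it
  appears.

* **Severity.**  A formulation tolerates only so much solubility loss
  (``tolerance_fold``); a risk is *severe* when the challenger is both
  plausibly reachable (p ≥ p_threshold) and costly (fold > tolerance),
  *moderate* when exactly one condition holds, *low* otherwise.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

from scipy.stats import norm

from .constants import R_KJ_MOL_K
from .landscape import LandscapeEntry, landscape_table

__all__ = [
    "RiskAssessment",
    "prob_more_stable",
    "solubility_ratio",
    "free_energy_from_solubility",
    "classify_risk",
    "assess_landscape",
    "render_report",
]

DEFAULT_P_THRESHOLD = 0.05
DEFAULT_TOLERANCE_FOLD = 1.05  # solution formulations tolerate only minor loss


@dataclass(frozen=True)
class RiskAssessment:
    """One challenger-vs-reference comparison."""

    reference_form: str
    challenger: str
    delta_f: float  # kJ/mol, challenger − reference; positive = challenger less stable
    sigma_pair: float  # kJ/mol
    p_more_stable: float
    solubility_fold: float  # solubility loss factor if the challenger appears
    severity: str


def prob_more_stable(delta_f: float, sigma_pair: float) -> float:
    """P(challenger more stable than reference) = Φ(−ΔF/σ)."""
    if sigma_pair <= 0:
        raise ValueError(f"sigma_pair must be positive, got {sigma_pair}")
    return float(norm.sf(delta_f / sigma_pair))


def solubility_ratio(delta_f: float, T: float = 300.0) -> float:
    """Solubility fold S_ref/S_new = exp(ΔF/RT) for a free-energy gap in kJ/mol."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return math.exp(delta_f / (R_KJ_MOL_K * T))


def free_energy_from_solubility(ratio: float, T: float = 300.0) -> float:
    """Free-energy gap ΔF = RT·ln(ratio) in kJ/mol from a solubility ratio."""
    if ratio <= 0:
        raise ValueError("solubility ratio must be positive")
    if T <= 0:
        raise ValueError("temperature must be positive")
    return R_KJ_MOL_K * T * math.log(ratio)


def classify_risk(
    p_more_stable: float,
    solubility_fold: float,
    tolerance_fold: float = DEFAULT_TOLERANCE_FOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> str:
    """Severity of one assessment: ``severe``, ``moderate`` or ``low``."""
    if tolerance_fold < 1:
        raise ValueError("tolerance_fold must be >= 1")
    plausible = p_more_stable >= p_threshold
    costly = solubility_fold > tolerance_fold
    if plausible and costly:
        return "severe"
    if plausible or costly:
        return "moderate"
    return "low"


def assess_pair(
    reference: LandscapeEntry,
    challenger: LandscapeEntry,
    T: float = 300.0,
    sigma_pair: Optional[float] = None,
    tolerance_fold: float = DEFAULT_TOLERANCE_FOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> RiskAssessment:
    """Assess one challenger against a reference form on the same landscape.

    ``sigma_pair`` defaults to the larger of the two entries' error bars.
    The solubility fold is the loss the reference formulation would suffer
    if the challenger appeared: exp(max(0, F_ref − F_chall)/RT).
    """
    delta_f = challenger.free_energy_rel - reference.free_energy_rel
    if sigma_pair is None:
        sigma_pair = max(challenger.sigma, reference.sigma)
    p = prob_more_stable(delta_f, sigma_pair)
    fold = solubility_ratio(max(0.0, -delta_f), T)
    return RiskAssessment(
        reference_form=reference.id,
        challenger=challenger.id,
        delta_f=delta_f,
        sigma_pair=sigma_pair,
        p_more_stable=p,
        solubility_fold=fold,
        severity=classify_risk(p, fold, tolerance_fold, p_threshold),
    )


def assess_landscape(
    entries: Sequence[LandscapeEntry],
    reference_id: str,
    T: float = 300.0,
    sigma_pair: Optional[float] = None,
    tolerance_fold: float = DEFAULT_TOLERANCE_FOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> list:
    """Assess every other entry against the named reference form.

    Returns assessments ordered by landscape rank of the challenger.
    """
    by_id = {e.id: e for e in entries}
    if reference_id not in by_id:
        raise ValueError(f"reference form {reference_id!r} not on the landscape")
    ref = by_id[reference_id]
    out = []
    for e in sorted(entries, key=lambda e: e.rank):
        if e.id == reference_id:
            continue
        out.append(assess_pair(ref, e, T, sigma_pair, tolerance_fold, p_threshold))
    return out


# ----------------------------------------------------------------------------
# report rendering


def render_report(
    entries: Sequence[LandscapeEntry],
    assessments: Sequence[RiskAssessment] = (),
    fmt: str = "text",
) -> str:
    """Render the landscape and assessments as text or JSON.

    Probabilities are shown to 2 significant figures in the text report and
    at full precision in JSON.  Output is deterministic for identical input.
    """
    if fmt == "json":
        payload = {
            "landscape": landscape_table(entries).to_dict(orient="records"),
            "assessments": [asdict(a) for a in assessments],
        }
        return json.dumps(payload, indent=2, sort_keys=True)
    if fmt != "text":
        raise ValueError(f"unknown report format {fmt!r}")

    lines = ["Crystal energy landscape", "=" * 24, ""]
    lines.append(
        f"{'rank':>4}  {'id':<14} {'sg':<10} {'density':>8} {'F_rel':>8} "
        f"{'sigma':>6}  {'fvib':<5} {'match':<10}"
    )
    for e in sorted(entries, key=lambda e: e.rank):
        lines.append(
            f"{e.rank:>4}  {e.id:<14} {e.spacegroup:<10} {e.density:>8.3f} "
            f"{e.free_energy_rel:>8.2f} {e.sigma:>6.2f}  "
            f"{'expl.' if e.fvib_explicit else 'shift':<5} {e.match_label or '-':<10}"
        )
    if assessments:
        lines += ["", "Risk assessments", "-" * 16, ""]
        lines.append(
            f"{'challenger':<14} {'vs':<14} {'dF':>7} {'P(more stable)':>15} "
            f"{'fold':>6}  severity"
        )
        for a in assessments:
            lines.append(
                f"{a.challenger:<14} {a.reference_form:<14} {a.delta_f:>7.2f} "
                f"{_sig2(a.p_more_stable):>15} {a.solubility_fold:>6.2f}  {a.severity}"
            )
    return "\n".join(lines) + "\n"


def _sig2(p: float) -> str:
    """Format a probability to 2 significant figures as a percentage."""
    return f"{p:.2g}" if p >= 0.1 else f"{100 * p:.2g}%"
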