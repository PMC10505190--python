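"""Two-step selection of target-matched nuclease variants, plus
single-mismatch guide-design enumeration.

Given a panel of variants graded by fidelity (each with a known fraction
of reference targets it can cleave), the screen first probes the target
with WT plus three variants whose cleavable fractions bracket the
quartiles, then fine-screens only the untested variants between the last
sufficiently active probe and the first insufficient one.  The
target-matched variant is the highest-fidelity variant still reaching the
activity floor; up to two top candidates are nominated for external
genome-wide off-target confirmation.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_ROUGH_MIN = 0.20
DEFAULT_FINE_MIN = 0.50
_BASES = "ACGT"


class ScreenError(ValueError):
    pass


@dataclass
class ScreenPanel:
    """Variant panel ordered by ascending fidelity (WT first).

    ``cleavable_fraction`` maps each variant to the fraction of reference
    targets it cleaves; fractions must be non-increasing along the panel.
    """

    variants: list
    cleavable_fraction: dict

    def __post_init__(self) -> None:
        missing = [v for v in self.variants if v not in self.cleavable_fraction]
        if missing:
            raise ScreenError(f"no cleavable fraction for panel members {missing}")
        fr = [self.cleavable_fraction[v] for v in self.variants]
        if any(b > a + 1e-12 for a, b in zip(fr, fr[1:])):
            raise ScreenError("cleavable fractions must be non-increasing with fidelity rank")

    @property
    def wt(self):
        return self.variants[0]

    def fidelity_index(self, variant) -> int:
        return self.variants.index(variant)

    @classmethod
    def from_map_fractions(cls, variant_order: list, cleaved_counts: dict, n_targets: int) -> "ScreenPanel":
        """Build a panel from a reference map's per-variant cleaved counts.

        ``variant_order`` is the map's fidelity ranking from most to least
        active; the panel stores it ascending in fidelity, WT first.
        """
        fractions = {v: cleaved_counts[v] / n_targets for v in variant_order}
        return cls(variants=list(variant_order), cleavable_fraction=fractions)


@dataclass
class Bracket:
    """Step-1 outcome: last sufficiently active probe and first insufficient."""

    lower: object  # highest-fidelity probe with activity >= threshold
    upper: object | None  # next probe up, None if the top probe was active
    measurements: dict
    threshold: float
    flag: str = ""


@dataclass
class ScreenOutcome:
    probes_tested: list  # (variant, activity) in fidelity order
    bracket: tuple
    target_matched: object | None
    candidates: list  # <= 2 ids for genome-wide off-target confirmation
    assays_used: int
    activity_min: float
    flag: str = ""

    def to_json_dict(self) -> dict:
        return {
            "probes_tested": [[str(v), float(a)] for v, a in self.probes_tested],
            "bracket": [None if b is None else str(b) for b in self.bracket],
            "target_matched": None if self.target_matched is None else str(self.target_matched),
            "candidates": [str(c) for c in self.candidates],
            "assays_used": self.assays_used,
            "activity_min": self.activity_min,
            "flag": self.flag,
        }


def plan_rough_screen(panel: ScreenPanel, quartiles: tuple = (0.75, 0.50, 0.25)) -> list:
    """Step-1 probe set: WT plus the three panel variants whose cleavable
    fractions are closest to the quartiles (ties -> lower fidelity).

    Probes are returned in ascending fidelity order.
    """
    if len(panel.variants) < 4:
        raise ScreenError("panel must contain WT plus at least 3 variants")
    chosen = [panel.wt]
    for q in quartiles:
        best, best_key = None, None
        for i, v in enumerate(panel.variants):
            if v in chosen:
                continue
            key = (abs(panel.cleavable_fraction[v] - q), i)  # tie -> lower fidelity
            if best_key is None or key < best_key:
                best, best_key = v, key
        chosen.append(best)
    return sorted(chosen, key=panel.fidelity_index)


def run_screen_step(
    oracle,
    probes: list,
    panel: ScreenPanel,
    activity_min: float = DEFAULT_ROUGH_MIN,
) -> Bracket:
    """Measure the probes and bracket the fidelity interval of the target.

    The bracket lower end is the top of the contiguous active run starting
    from the lowest-fidelity probe; non-monotone measurements (an active
    probe above an inactive one) are reported via a warning and the flag.
    A target where no probe reaches the threshold is flagged
    low-cleavability and bracketed between WT and the first probe.
    """
    probes = sorted(probes, key=panel.fidelity_index)
    measurements = {v: float(oracle(v)) for v in probes}
    active = [measurements[v] >= activity_min for v in probes]
    flag = ""
    run_end = 0
    while run_end < len(probes) and active[run_end]:
        run_end += 1
    if any(active[run_end:]):
        flag = "non-monotone measurements above the active run: " + ", ".join(
            str(probes[i]) for i in range(run_end, len(probes)) if active[i]
        )
        warnings.warn(flag, stacklevel=2)
    if run_end == 0:
        return Bracket(
            lower=panel.wt,
            upper=probes[1] if len(probes) > 1 else None,
            measurements=measurements,
            threshold=activity_min,
            flag="low-cleavability target: no probe active",
        )
    lower = probes[run_end - 1]
    upper = probes[run_end] if run_end < len(probes) else None
    return Bracket(lower=lower, upper=upper, measurements=measurements, threshold=activity_min, flag=flag)


def plan_fine_screen(panel: ScreenPanel, bracket: Bracket) -> list:
    """Step-2 probe set: untested panel variants strictly inside the bracket.

    An open upper bracket (top probe active) yields every untested variant
    above the last active probe.  Returned in ascending fidelity order.
    """
    lo = panel.fidelity_index(bracket.lower)
    hi = panel.fidelity_index(bracket.upper) if bracket.upper is not None else len(panel.variants)
    tested = set(bracket.measurements)
    return [v for v in panel.variants[lo + 1 : hi] if v not in tested]


def select_target_matched(
    measurements: dict,
    panel: ScreenPanel,
    activity_min: float = DEFAULT_FINE_MIN,
) -> ScreenOutcome:
    """Pick the highest-fidelity sufficiently active variant.

    Measurements are scanned as a contiguous active run from the
    lowest-fidelity measured variant upward (the trusted resolution of
    noisy, non-monotone data); the run's top is the target-matched
    variant and the top two run members are the candidates for external
    off-target confirmation.
    """
    ordered = sorted(measurements, key=panel.fidelity_index)
    probes_tested = [(v, measurements[v]) for v in ordered]
    run = []
    for v in ordered:
        if measurements[v] >= activity_min:
            run.append(v)
        else:
            break
    leftover_active = [v for v in ordered[len(run) :] if measurements[v] >= activity_min]
    flag = ""
    if leftover_active:
        flag = "non-monotone measurements above the active run: " + ", ".join(map(str, leftover_active))
        warnings.warn(flag, stacklevel=2)
    if not run or (len(run) == 1 and run[0] == panel.wt):
        return ScreenOutcome(
            probes_tested=probes_tested,
            bracket=(panel.wt, ordered[1] if len(ordered) > 1 else None),
            target_matched=panel.wt if run else None,
            candidates=[],
            assays_used=len(ordered),
            activity_min=activity_min,
            flag="no variant available below target's cleavability rank"
            if run
            else "low-cleavability target: nothing active",
        )
    matched = run[-1]
    above = [v for v in ordered if panel.fidelity_index(v) > panel.fidelity_index(matched)]
    upper = above[0] if above else None
    candidates = [v for v in run[-2:] if v != panel.wt][::-1]  # highest fidelity first
    return ScreenOutcome(
        probes_tested=probes_tested,
        bracket=(matched, upper),
        target_matched=matched,
        candidates=candidates[:2],
        assays_used=len(ordered),
        activity_min=activity_min,
        flag=flag,
    )


def two_step_screen(
    panel: ScreenPanel,
    oracle,
    *,
    rough_min: float = DEFAULT_ROUGH_MIN,
    fine_min: float = DEFAULT_FINE_MIN,
    quartiles: tuple = (0.75, 0.50, 0.25),
) -> ScreenOutcome:
    """Run the full two-step screen against an activity oracle.

    ``oracle(variant)`` must return the WT-normalized on-target activity.
    Step 1 brackets with the rough threshold; step 2 measures the variants
    inside the bracket and the final selection applies ``fine_min``.
    """
    probes = plan_rough_screen(panel, quartiles)
    bracket = run_screen_step(oracle, probes, panel, activity_min=rough_min)
    measurements = dict(bracket.measurements)
    for v in plan_fine_screen(panel, bracket):
        measurements[v] = float(oracle(v))
    outcome = select_target_matched(measurements, panel, activity_min=fine_min)
    if bracket.flag and not outcome.flag:
        outcome.flag = bracket.flag
    return outcome


def full_panel_select(
    panel: ScreenPanel, oracle, activity_min: float = DEFAULT_FINE_MIN
) -> ScreenOutcome:
    """Exhaustive reference: measure every panel member and select."""
    measurements = {v: float(oracle(v)) for v in panel.variants}
    return select_target_matched(measurements, panel, activity_min=activity_min)


# ---------------------------------------------------------------------------
# single-mismatch guide design


def single_mismatch_spacers(spacer: str, positions=None) -> list:
    """Enumerate every single-nucleotide mismatch variant of a spacer.

    Positions are 1-based counting from the PAM-proximal end (position 1
    is adjacent to the PAM; for a 20-mer, positions 18-20 are PAM-distal).
    ``positions=None`` probes every position.  Returns a list of
    (position, alt_base, mismatched_spacer) with the 3 alternative bases
    per probed position.
    """
    spacer = spacer.upper()
    n = len(spacer)
    if any(b not in _BASES for b in spacer):
        raise ScreenError(f"spacer contains non-ACGT characters: {spacer}")
    if positions is None:
        positions = range(1, n + 1)
    out = []
    for p in positions:
        p = int(p)
        if not 1 <= p <= n:
            raise ScreenError(f"spacer position {p} outside 1..{n}")
        idx = n - p  # position 1 = 3' (PAM-proximal) end
        for alt in _BASES:
            if alt == spacer[idx]:
                continue
            out.append((p, alt, spacer[:idx] + alt + spacer[idx + 1 :]))
    return out


def design_mismatch_screen(spacers: dict, positions=None) -> pd.DataFrame:
    """Enumerate the mismatched guides of a screen design.

    ``spacers`` maps target_id -> 20-nt spacer.  Returns one row per
    distinct mismatched sgRNA with columns (target_id, position, alt_base,
    spacer).
    """
    rows = []
    for tid, spacer in spacers.items():
        for p, alt, seq in single_mismatch_spacers(spacer, positions):
            rows.append({"target_id": tid, "position": p, "alt_base": alt, "spacer": seq})
    df = pd.DataFrame(rows)
    if len(df) and df.duplicated(["target_id", "spacer"]).any():
        raise ScreenError("duplicate mismatched spacers in design")
    return df


def random_spacers(n: int, length: int = 20, seed: int = 0) -> dict:
    """Deterministic random spacer set for design arithmetic and simulations."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 77]))
    return {
        f"T{i + 1:03d}": "".join(rng.choice(list(_BASES), size=length))
        for i in range(n)
    }
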