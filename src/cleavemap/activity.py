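"""Normalization and cleavage calling for variant x target activity tables.

Raw activity tables are long-format records of replicate measurements
(percent EGFP-negative cells or percent indel reads) for nuclease variants
on target sites, together with dead-nuclease / non-targeting background
controls.  This module turns them into WT-normalized, two-decimal activity
matrices, calls cleaved/not-cleaved at a threshold, and applies the
dataset-specific filters used for the mismatch-mixture screen and the
external high-throughput reanalysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns required of a long-format raw activity table.
RAW_COLUMNS = (
    "experiment_id",
    "variant_id",
    "target_id",
    "value",
    "replicate",
    "modality",
    "day",
    "is_background",
)

#: Default cleavage-call threshold on WT-normalized activity.
DEFAULT_THETA = 0.20


class ActivityError(ValueError):
    """Raised on malformed or incomplete activity tables."""


def validate_raw_table(raw: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format raw activity table.

    Requires the mandatory columns (``day`` and ``modality`` may be absent,
    they are filled with defaults), values within [0, 100], and a boolean
    ``is_background`` column.  Returns a normalized copy.
    """
    df = raw.copy()
    for col in ("experiment_id", "variant_id", "target_id", "value"):
        if col not in df.columns:
            raise ActivityError(f"raw table is missing required column {col!r}")
    if "replicate" not in df.columns:
        df["replicate"] = 1
    if "modality" not in df.columns:
        df["modality"] = "disruption"
    if "day" not in df.columns:
        df["day"] = pd.NA
    if "is_background" not in df.columns:
        df["is_background"] = False
    df["is_background"] = df["is_background"].astype(bool)
    df["value"] = df["value"].astype(float)
    bad = df[(df["value"] < 0) | (df["value"] > 100)]
    if len(bad):
        raise ActivityError(
            f"{len(bad)} replicate values outside [0, 100]; first offender: "
            f"{bad.iloc[0].to_dict()}"
        )
    mods = set(df["modality"].unique()) - {"disruption", "ngs"}
    if mods:
        raise ActivityError(f"unknown modality values: {sorted(mods)}")
    return df


@dataclass
class ActivityMatrix:
    """WT-normalized variant x target activity matrix.

    ``values`` holds unitless WT-normalized activities quantized to two
    decimals (rows = variants, columns = targets).  Undefined cells (e.g.
    WT signal not above background) are NaN and stay NaN downstream.
    """

    values: pd.DataFrame
    theta: float = DEFAULT_THETA
    provenance: tuple = ()

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if (finite < 0).any():
            raise ActivityError("normalized activities must be non-negative")
        if not np.allclose(finite, np.round(finite, 2), atol=1e-9):
            raise ActivityError("normalized activities must be quantized to 2 decimals")

    @property
    def variant_ids(self) -> list:
        return list(self.values.index)

    @property
    def target_ids(self) -> list:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        out = self.values.map(lambda x: "" if pd.isna(x) else f"{x:.2f}")
        out.to_csv(path, sep="\t", index_label="variant_id")

    @classmethod
    def from_tsv(cls, path, theta: float = DEFAULT_THETA) -> "ActivityMatrix":
        df = pd.read_csv(path, sep="\t", index_col="variant_id")
        return cls(values=df.astype(float), theta=theta, provenance=(str(path),))


@dataclass
class CallMatrix:
    """Binary cleaved / not-cleaved calls with the threshold that made them."""

    calls: pd.DataFrame  # nullable boolean; NA = undefined cell
    theta: float

    @property
    def variant_ids(self) -> list:
        return list(self.calls.index)

    @property
    def target_ids(self) -> list:
        return list(self.calls.columns)


def _round2(x: np.ndarray) -> np.ndarray:
    # round-half-up at the second decimal, as fixed-point tables do
    return np.floor(x * 100.0 + 0.5) / 100.0


def normalize_to_wt(
    raw: pd.DataFrame,
    wt_label: str = "WT",
    *,
    per_replicate: bool = False,
) -> ActivityMatrix:
    """Background-subtract and WT-normalize a raw activity table.

    Per (experiment, target): the mean background-control value is
    subtracted from every treatment mean (the WT treatment included), each
    variant's net value is divided by the net WT value, negatives are
    clipped to zero, and results are rounded to two decimals.

    With ``per_replicate=True`` each replicate is normalized against the
    per-replicate-matched WT value first and replicates are averaged after.

    Raises :class:`ActivityError` when a target lacks a WT entry.  Targets
    where the WT signal does not exceed background yield NaN (undefined),
    never silently zero.
    """
    df = validate_raw_table(raw)
    treatments = df[~df["is_background"]]
    if wt_label not in set(treatments["variant_id"]):
        raise ActivityError(f"WT label {wt_label!r} not present in table")

    variant_ids = list(dict.fromkeys(treatments["variant_id"]))
    target_ids = list(dict.fromkeys(treatments["target_id"]))
    out = pd.DataFrame(np.nan, index=variant_ids, columns=target_ids, dtype=float)

    for (exp, tgt), block in df.groupby(["experiment_id", "target_id"], sort=False):
        bg_rows = block[block["is_background"]]
        tr_rows = block[~block["is_background"]]
        if bg_rows.empty:
            raise ActivityError(f"no background control for target {tgt!r} in experiment {exp!r}")
        wt_rows = tr_rows[tr_rows["variant_id"] == wt_label]
        if wt_rows.empty:
            raise ActivityError(f"no WT entry for target {tgt!r} in experiment {exp!r}")
        bg = bg_rows["value"].mean()

        if per_replicate:
            wt_by_rep = wt_rows.set_index("replicate")["value"] - bg
            for vid, vrows in tr_rows.groupby("variant_id", sort=False):
                ratios = []
                for _, row in vrows.iterrows():
                    wt_net = wt_by_rep.get(row["replicate"], np.nan)
                    if not np.isfinite(wt_net) or wt_net <= 0:
                        ratios.append(np.nan)
                    else:
                        ratios.append(max(row["value"] - bg, 0.0) / wt_net)
                arr = np.asarray(ratios, dtype=float)
                if np.isfinite(arr).any():
                    out.loc[vid, tgt] = float(_round2(max(np.nanmean(arr), 0.0)))
                else:
                    out.loc[vid, tgt] = np.nan
        else:
            wt_net = wt_rows["value"].mean() - bg
            for vid, vrows in tr_rows.groupby("variant_id", sort=False):
                if wt_net <= 0:
                    out.loc[vid, tgt] = np.nan  # undefined, flagged by NaN
                    continue
                net = vrows["value"].mean() - bg
                out.loc[vid, tgt] = float(_round2(max(net, 0.0) / wt_net))

    return ActivityMatrix(
        values=out,
        provenance=tuple(sorted(set(df["experiment_id"].astype(str)))),
    )


def call_cleavage(matrix: ActivityMatrix, theta: float = DEFAULT_THETA) -> CallMatrix:
    """Call each cell cleaved (value >= theta) or not-cleaved (< theta).

    Thresholding happens on the stored two-decimal values, so 0.195 has
    already been rounded to 0.20 and is called cleaved.  NaN cells stay NA.
    """
    if not (0.0 < theta <= 2.0):
        raise ActivityError(f"threshold theta={theta} outside (0, 2]")
    vals = matrix.values
    calls = (vals >= theta).astype("boolean")
    calls = calls.mask(vals.isna(), pd.NA)
    return CallMatrix(calls=calls, theta=theta)


def aggregate_mismatch_screen(
    on_table: pd.DataFrame,
    off_table: pd.DataFrame,
    *,
    on_min: float = 0.20,
    specificity_min: float = 0.70,
) -> pd.DataFrame:
    """Aggregate off-target measurements against their on-target anchors.

    ``on_table`` has one row per (variant_id, target_id) with columns
    ``on_value`` (raw activity, the normalization denominator) and
    ``on_norm`` (WT-normalized on-target activity used for gating).
    ``off_table`` is long format with columns (variant_id, target_id,
    probe, value) where ``probe`` names a mismatch position / off-target
    set; replicate off-target values for the same probe are averaged
    before division by the on-target value.

    Output rows carry ``off_target_norm`` plus two masks: ``masked``
    (on-target normalized activity below ``on_min``: not determined) and
    ``spec_masked`` (below ``specificity_min``: excluded from specificity
    summaries).  Masked entries have ``off_target_norm`` = NaN so they can
    never contribute to a downstream mean.
    """
    required_on = {"variant_id", "target_id", "on_value", "on_norm"}
    required_off = {"variant_id", "target_id", "probe", "value"}
    if missing := required_on - set(on_table.columns):
        raise ActivityError(f"on_table missing columns {sorted(missing)}")
    if missing := required_off - set(off_table.columns):
        raise ActivityError(f"off_table missing columns {sorted(missing)}")

    anchors = on_table.set_index(["variant_id", "target_id"])
    if anchors.index.has_duplicates:
        raise ActivityError("on_table has duplicate (variant, target) anchors")

    rows = []
    grouped = off_table.groupby(["variant_id", "target_id", "probe"], sort=False)
    for (vid, tgt, probe), block in grouped:
        try:
            anchor = anchors.loc[(vid, tgt)]
        except KeyError:
            raise ActivityError(
                f"off-target entry ({vid!r}, {tgt!r}) has no matching on-target"
            ) from None
        off_mean = float(block["value"].mean())
        on_norm = float(anchor["on_norm"])
        masked = not (on_norm >= on_min)
        spec_masked = not (on_norm >= specificity_min)
        if masked or anchor["on_value"] <= 0:
            norm = np.nan
        else:
            norm = off_mean / float(anchor["on_value"])
        rows.append(
            {
                "variant_id": vid,
                "target_id": tgt,
                "probe": probe,
                "on_norm": on_norm,
                "off_target_norm": norm,
                "masked": masked,
                "spec_masked": spec_masked,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class KimFilterResult:
    """Targets passing the external-dataset filters plus per-filter removals."""

    table: pd.DataFrame
    n_input: int
    removed_not_perfect: int
    removed_missing_data: int
    removed_low_wt: int

    @property
    def n_retained(self) -> int:
        return len(self.table)


def filter_kim_targets(
    table: pd.DataFrame,
    *,
    nuclease_columns: list | None = None,
    wt_column: str = "WT",
    perfect_column: str = "perfect_n20",
    min_wt_indel: float = 15.0,
) -> KimFilterResult:
    """Apply the three target filters used for the external-dataset reanalysis.

    1. keep targets interrogated with perfectly matching tRNA-N20
       protospacers (``perfect_column`` truthy);
    2. drop targets lacking data for any nuclease column;
    3. drop targets the WT cleaved with indel occurrence below
       ``min_wt_indel`` percent (strictly below 15% is removed; 15.0 stays).

    Filters apply sequentially; input row order is preserved.
    """
    if perfect_column not in table.columns:
        raise ActivityError(f"missing required column {perfect_column!r}")
    if nuclease_columns is None:
        meta = {perfect_column, "target_id"}
        nuclease_columns = [c for c in table.columns if c not in meta]
    missing = [c for c in nuclease_columns if c not in table.columns]
    if missing:
        raise ActivityError(f"missing required columns {missing}")
    if wt_column not in nuclease_columns:
        raise ActivityError(f"WT column {wt_column!r} not among nuclease columns")

    step1 = table[table[perfect_column].astype(bool)]
    step2 = step1.dropna(subset=nuclease_columns)
    step3 = step2[step2[wt_column].astype(float) >= min_wt_indel]
    return KimFilterResult(
        table=step3.copy(),
        n_input=len(table),
        removed_not_perfect=len(table) - len(step1),
        removed_missing_data=len(step1) - len(step2),
        removed_low_wt=len(step2) - len(step3),
    )
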