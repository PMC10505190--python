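"""Pipeline configuration and end-to-end wiring.

A single JSON config drives simulate -> normalize -> call -> order ->
fit -> score -> screen with a fixed seed; identical configs produce
byte-identical TSV/JSON outputs (timestamp-free, fixed float formats,
provenance carries the config hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import activity, latent, rule, screen

log = logging.getLogger("cleavemap")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 1
    n_targets: int = 50
    n_variants: int = 19
    theta: float = 0.20
    rough_min: float = 0.20
    fine_min: float = 0.50
    boundary_mode: str = "min_misclass"  # or "count_matched"
    exhaustive_limit: int = 8
    c_range: tuple = (0.0, 10.0)
    cleaved_band: tuple = (0.70, 1.20)
    residual_scale: float = 0.03
    softness: float = 0.0
    replicates: int = 3
    background_pct: float = 2.0
    wt_raw_pct: float = 50.0
    replicate_jitter: float = 0.0
    screen_targets: int = 5

    def __post_init__(self) -> None:
        if not (0.0 < self.theta <= 2.0):
            raise ConfigError("theta must be in (0, 2]")
        if self.boundary_mode not in ("min_misclass", "count_matched"):
            raise ConfigError(f"unknown boundary_mode {self.boundary_mode!r}")
        if self.n_targets < 1 or self.n_variants < 2:
            raise ConfigError("need at least 1 target and 2 variants (WT + 1)")
        if self.wt_raw_pct <= self.background_pct:
            raise ConfigError("wt_raw_pct must exceed background_pct")
        if not (0 < self.rough_min <= self.fine_min <= 1.5):
            raise ConfigError("need 0 < rough_min <= fine_min")
        self.c_range = tuple(self.c_range)
        self.cleaved_band = tuple(self.cleaved_band)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def canonical_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, separators=(",", ":"))

    def digest(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage in order, writing a deterministic artifact bundle.

    Returns a manifest dict (also written as ``provenance.json``).  A
    failing stage aborts with the stage named.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        params = latent.sample_model(
            config.n_targets,
            config.n_variants,
            c_range=config.c_range,
            cleaved_band=config.cleaved_band,
            residual_scale=config.residual_scale,
            softness=config.softness,
            seed=config.seed,
        )
        raw = latent.simulate_disruption_matrix(
            params,
            replicates=config.replicates,
            background_pct=config.background_pct,
            wt_raw_pct=config.wt_raw_pct,
            replicate_jitter=config.replicate_jitter,
            theta=config.theta,
        )
        (outdir / "params.json").write_text(
            json.dumps(params.to_json_dict(), indent=1, sort_keys=True)
        )
        raw.to_csv(outdir / "raw.tsv", sep="\t", index=False, float_format="%.6f")

        stage = "normalize"
        matrix = activity.normalize_to_wt(raw)
        matrix.to_tsv(outdir / "matrix.tsv")

        stage = "call"
        calls = activity.call_cleavage(matrix, config.theta)

        stage = "order+fit"
        rmap = rule.build_map(
            matrix,
            config.theta,
            exhaustive_limit=config.exhaustive_limit,
            count_matched=config.boundary_mode == "count_matched",
        )
        rmap.to_tsv(outdir / "map.tsv")

        stage = "score"
        fit = rule.score_rule_fit(rmap)
        rocs = rule.all_variant_rocs(rmap)
        fit_dict = {
            "tp": fit.tp,
            "fp": fit.fp,
            "tn": fit.tn,
            "fn": fit.fn,
            "sensitivity": None if not fit.defined else round(fit.sensitivity, 6),
            "specificity": None if not fit.defined else round(fit.specificity, 6),
            "gmean": None if not fit.defined else round(fit.gmean, 6),
            "n_outliers": fit.n_outliers,
            "boundary_monotone": rule.boundary_is_monotone(rmap),
        }
        (outdir / "rulefit.json").write_text(json.dumps(fit_dict, indent=1, sort_keys=True))
        roc_rows = []
        for vid, roc in rocs.items():
            for fpr, tpr in roc.points:
                roc_rows.append(
                    {
                        "variant_id": vid,
                        "fpr": round(fpr, 6),
                        "tpr": round(tpr, 6),
                        "auc": "" if not roc.defined else round(roc.auc, 6),
                    }
                )
        pd.DataFrame(roc_rows).to_csv(outdir / "roc.tsv", sep="\t", index=False)

        stage = "screen"
        counts = {
            v: int(rmap.calls.loc[v].fillna(False).sum()) for v in rmap.variant_order
        }
        panel = screen.ScreenPanel.from_map_fractions(
            rmap.variant_order, counts, len(rmap.target_order)
        )
        outcomes = {}
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4242]))
        probe_targets = sorted(
            rng.choice(params.target_ids, size=min(config.screen_targets, len(params.target_ids)), replace=False)
        )
        vidx = {v: i for i, v in enumerate(params.variant_ids)}
        for tid in probe_targets:
            ti = params.target_ids.index(tid)

            def oracle(v, ti=ti):
                if vidx[v] == 0:
                    return 1.0
                cleaved = bool(params.c[ti] > params.f[vidx[v]])
                return latent._cell_activity(params, vidx[v], ti, cleaved, params.seed, config.theta)

            outcomes[tid] = screen.two_step_screen(
                panel, oracle, rough_min=config.rough_min, fine_min=config.fine_min
            ).to_json_dict()
        (outdir / "screen.json").write_text(json.dumps(outcomes, indent=1, sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": json.loads(config.canonical_json()),
        "config_digest": config.digest(),
        "seed": config.seed,
        "outputs": sorted(
            p.name for p in outdir.iterdir() if p.name != "provenance.json"
        ),
    }
    (outdir / "provenance.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info("pipeline complete: %s (digest %s)", outdir, manifest["config_digest"])
    return manifest
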