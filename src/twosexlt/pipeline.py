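"""End-to-end reproducible run: simulate -> life table -> bootstrap ->
group statistics -> correlation.

Every stage draws its seed deterministically from one master seed, so the
whole run — and any stage rerun in isolation — is reproducible bit for bit.
The run writes a manifest listing every output file with its stage, seed
and SHA-256 checksum; identical configurations produce identical
checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import correlation, groupstats, simulate
from .bootstrap import bootstrap_lifetable, bootstrap_results_frame
from .cohort import read_cohort, write_cohort
from .lifetable import TwoSexLifeTable

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

log = logging.getLogger("twosexlt")

_STAGE_IDS = {"simulate": 1, "lifetable": 2, "bootstrap": 3,
              "compare": 4, "correlate": 5}


def stage_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed split from the master seed (< 2^31)."""
    ss = np.random.SeedSequence([int(master_seed), _STAGE_IDS[stage], int(index)])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """Declarative configuration for one pipeline run."""

    master_seed: int
    out_dir: Path
    treatments: tuple[str, ...] = simulate.TREATMENTS
    cohort_n: int = 20
    B: int = 100_000
    endpoints: tuple[str, ...] = (
        simulate.PLANT_ENDPOINTS + simulate.INSECT_ENDPOINTS
    )
    replicates: int = 3
    run_simulate: bool = True
    run_lifetable: bool = True
    run_bootstrap: bool = True
    run_compare: bool = True
    run_correlate: bool = True

    def __post_init__(self) -> None:
        if self.master_seed is None:
            raise ValueError("a master seed is mandatory")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        self.out_dir = Path(self.out_dir)
        self.treatments = tuple(str(t) for t in self.treatments)
        self.endpoints = tuple(self.endpoints)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def resolved(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["out_dir"] = str(d["out_dir"])
        d["treatments"] = list(d["treatments"])
        d["endpoints"] = list(d["endpoints"])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.resolved(), "outputs": []}

    def register(path: Path, stage: str, seed: int | None) -> None:
        manifest["outputs"].append(
            {"file": str(path.relative_to(out)), "stage": stage,
             "seed": seed, "sha256": _sha256(path)}
        )

    cohorts = {}
    try:
        if config.run_simulate:
            for k, trt in enumerate(config.treatments):
                seed = stage_seed(config.master_seed, "simulate", k)
                params = simulate.default_params(trt, n=config.cohort_n)
                cohort = simulate.simulate_cohort(params, seed=seed)
                cpath = out / f"cohort_{trt}.csv"
                fpath = out / f"fecundity_{trt}.csv"
                write_cohort(cohort, cpath, fpath)
                register(cpath, "simulate", seed)
                register(fpath, "simulate", seed)
                cohorts[trt] = cohort
                log.info("simulated treatment %s (n=%d, seed=%d)",
                         trt, cohort.n, seed)
            ep_seed = stage_seed(config.master_seed, "simulate", 1000)
            ep_params = [simulate.default_endpoint_params(e, config.replicates)
                         for e in config.endpoints]
            endpoints = simulate.simulate_endpoints(ep_params, seed=ep_seed)
            endpoints = endpoints[
                endpoints["treatment"].isin(config.treatments)
            ].reset_index(drop=True)
            epath = out / "endpoints.csv"
            endpoints.to_csv(epath, index=False)
            register(epath, "simulate", ep_seed)
        else:
            for trt in config.treatments:
                cohorts[trt] = read_cohort(out / f"cohort_{trt}.csv",
                                           out / f"fecundity_{trt}.csv")
            endpoints = pd.read_csv(out / "endpoints.csv")

        results = {}
        if config.run_lifetable:
            for trt, cohort in cohorts.items():
                res = TwoSexLifeTable(cohort).fit()
                results[trt] = res
                cpath = out / f"lifetable_curves_{trt}.tsv"
                mpath = out / f"lifetable_matrix_{trt}.tsv"
                res.to_tsv(cpath, mpath)
                ppath = out / f"params_{trt}.json"
                ppath.write_text(res.params_json(), encoding="utf-8")
                for p in (cpath, mpath, ppath):
                    register(p, "lifetable", None)
                log.info("life table for %s: r=%.4f R0=%.2f", trt,
                         res.params["r"], res.params["R0"])

        if config.run_bootstrap:
            for k, (trt, cohort) in enumerate(cohorts.items()):
                seed = stage_seed(config.master_seed, "bootstrap", k)
                boot = bootstrap_lifetable(cohort, B=config.B, seed=seed)
                bpath = out / f"bootstrap_{trt}.tsv"
                bootstrap_results_frame(boot).to_csv(bpath, sep="\t", index=False)
                register(bpath, "bootstrap", seed)
                log.info("bootstrap for %s: B=%d seed=%d", trt, config.B, seed)

        if config.run_compare:
            frames = []
            for name, sub in endpoints.groupby("endpoint"):
                cmp_res = groupstats.compare_groups(sub, endpoint=str(name))
                frames.append(cmp_res.to_frame())
                log.info("compare %s: %s p=%.3g", name, cmp_res.test_used,
                         cmp_res.pvalue)
            gpath = out / "comparisons.tsv"
            pd.concat(frames, ignore_index=True).to_csv(gpath, sep="\t", index=False)
            register(gpath, "compare", None)

        if config.run_correlate and len(config.treatments) < 3:
            log.warning("correlation skipped: need >= 3 treatments, have %d",
                        len(config.treatments))
        elif config.run_correlate:
            long = endpoints.rename(columns={"endpoint": "variable"})[
                ["treatment", "variable", "value"]
            ]
            rows = [long]
            if results:
                demo = []
                for trt, res in results.items():
                    for var in ("r", "F", "R0", "ovi_days"):
                        demo.append({"treatment": trt, "variable": var,
                                     "value": res.params[var]})
                rows.append(pd.DataFrame(demo))
            means = correlation.treatment_means_table(pd.concat(rows,
                                                                ignore_index=True))
            M = correlation.pearson_matrix(means)
            mpath = out / "correlation_matrix.tsv"
            M.matrix.to_csv(mpath, sep="\t")
            register(mpath, "correlate", None)
            order = [v for v in list(simulate.PLANT_ENDPOINTS)
                     + list(simulate.INSECT_ENDPOINTS)
                     + ["r", "F", "R0", "ovi_days"] if v in M.matrix.columns]
            hpath = out / "correlation_heatmap.png"
            correlation.export_heatmap(M, hpath, order=order)
            register(hpath, "correlate", None)
    except Exception as exc:
        manifest["failed"] = {"stage": _current_stage(manifest), "cause": str(exc)}
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
        )
        raise

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True),
                     encoding="utf-8")
    return manifest


def _current_stage(manifest: dict) -> str:
    if manifest["outputs"]:
        return manifest["outputs"][-1]["stage"]
    return "simulate"
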