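"""Tissue presets, table and config I/O, and the end-to-end pipeline.

Cohort tables are plain TSV with a fixed header
(``mouse_id  crypts_scored  clones_observed  kind  chase_day``); counts
are proportions-free integers, and fraction-valued inputs elsewhere in
the package are proportions in [0, 1], never percent, to avoid silent
100x errors.  Run configurations are flat YAML/JSON documents; every
run writes back a fully resolved copy of its configuration (defaults
materialised, preset constants expanded, seed included) so it can be
reproduced from that file alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bayes import CloneFractionModel, CloneFractionResults, HyperPriors, MCMCConfig
from .cohort import COLUMNS, CohortTable
from .drift import DriftParams, Observable

__all__ = [
    "TissuePreset",
    "PRESETS",
    "tissue_preset",
    "load_cohort_table",
    "write_cohort_table",
    "fold_change",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger("cryptdrift")


@dataclass(frozen=True)
class TissuePreset:
    """Named tissue with its drift constants and default observable.

    The small-intestine presets score any surviving clone (ribbon
    clones are not size-resolved there); the colon preset scores only
    wholly populated crypts.
    """

    name: str
    params: DriftParams
    default_kind: Observable


PRESETS: dict[str, TissuePreset] = {
    "proximal_si": TissuePreset(
        "proximal_si", DriftParams(N=5, lam=0.1, tau=5.0),
        Observable.ANY_SURVIVING,
    ),
    "distal_si": TissuePreset(
        "distal_si", DriftParams(N=6, lam=0.2, tau=5.0),
        Observable.ANY_SURVIVING,
    ),
    "colon": TissuePreset(
        "colon", DriftParams(N=7, lam=0.3, tau=1.0),
        Observable.WHOLE_ONLY,
    ),
}


def tissue_preset(name: str) -> TissuePreset:
    """Look up a tissue preset by name."""
    key = str(name).strip().lower()
    if key not in PRESETS:
        raise KeyError(
            f"unknown tissue preset {name!r}; valid presets: "
            + ", ".join(sorted(PRESETS))
        )
    return PRESETS[key]


def load_cohort_table(path: str | Path) -> CohortTable:
    """Read and validate a TSV cohort table; row order is preserved."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"mouse_id": str})
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty, not a cohort table") from None
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    try:
        return CohortTable(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_cohort_table(table: CohortTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.df.to_csv(path, sep="\t", index=False)
    return path


def fold_change(numerator: float, denominator: float) -> tuple[float, str]:
    """Exact ratio plus a nearest-integer '-fold' report string.

    Units must match (both percent or both proportions); the ratio is
    unit-free either way.
    """
    if not denominator > 0:
        raise ValueError(f"denominator must be > 0, got {denominator!r}")
    if numerator < 0:
        raise ValueError(f"numerator must be >= 0, got {numerator!r}")
    ratio = numerator / denominator
    return ratio, f"{round(ratio):d}-fold"


@dataclass(frozen=True)
class RunConfig:
    """Resolved settings for one fit run.

    Exactly one of ``preset`` / ``params`` is supplied; the observable
    kind defaults to the preset's convention and may be overridden.
    Chase days live in the data rows, not here.
    """

    input_table: str
    output_dir: str
    preset: str | None = None
    params: DriftParams | None = None
    kind: Observable | str | None = None
    priors: HyperPriors = HyperPriors()
    mcmc: MCMCConfig = MCMCConfig()
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.preset is None) == (self.params is None):
            raise ValueError(
                "supply exactly one of 'preset' or explicit 'params'"
            )
        if self.kind is not None:
            object.__setattr__(self, "kind", Observable.parse(self.kind))

    def resolved_params(self) -> DriftParams:
        if self.params is not None:
            return self.params
        return tissue_preset(self.preset).params

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a flat YAML (or JSON, a YAML subset) config document."""
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        seed = int(raw.pop("seed", 0))
        known_priors = {f.name for f in dataclasses.fields(HyperPriors)}
        known_mcmc = {f.name for f in dataclasses.fields(MCMCConfig)}
        priors = HyperPriors(
            **{k: raw.pop(k) for k in list(raw) if k in known_priors}
        )
        mcmc_kw = {k: raw.pop(k) for k in list(raw) if k in known_mcmc}
        preset = raw.pop("preset", None)
        params = None
        explicit = {k: raw.pop(k) for k in ("N", "lam", "tau") if k in raw}
        if preset is None and explicit:
            params = DriftParams(
                N=int(explicit["N"]), lam=float(explicit["lam"]),
                tau=float(explicit.get("tau", 0.0)),
            )
        # a resolved config carries both the preset name and its expanded
        # constants; the preset wins and the constants must agree
        if preset is not None and explicit:
            expanded = tissue_preset(preset).params
            if explicit != {"N": expanded.N, "lam": expanded.lam,
                            "tau": expanded.tau}:
                raise ValueError(
                    f"explicit constants {explicit} contradict preset "
                    f"{preset!r} ({expanded})"
                )
        mcmc = MCMCConfig(**{**mcmc_kw, "seed": seed})
        cfg = cls(
            input_table=str(raw.pop("input_table")),
            output_dir=str(raw.pop("output_dir")),
            preset=preset,
            params=params,
            kind=raw.pop("kind", None),
            priors=priors,
            mcmc=mcmc,
            seed=seed,
        )
        if raw:
            raise ValueError(f"unknown config key(s): {sorted(raw)}")
        return cfg

    def to_mapping(self) -> dict:
        """Fully materialised flat mapping, reproducing this run."""
        p = self.resolved_params()
        out = {
            "input_table": self.input_table,
            "output_dir": self.output_dir,
            "preset": self.preset,
            "N": p.N,
            "lam": p.lam,
            "tau": p.tau,
            "kind": self.kind.value if self.kind else None,
            "seed": self.seed,
        }
        out.update(dataclasses.asdict(self.priors))
        for f in dataclasses.fields(MCMCConfig):
            out[f.name] = getattr(self.mcmc, f.name)
        out["seed"] = self.seed
        return out


def _write_draws_tsv(res: CloneFractionResults, path: Path) -> None:
    n_chains, n_samples = res.draws["v"].shape
    cols = {
        "chain": np.repeat(np.arange(n_chains), n_samples),
        "draw": np.tile(np.arange(n_samples), n_chains),
        "v": res.draws["v"].reshape(-1),
        "eta": res.draws["eta"].reshape(-1),
        "sigma": res.draws["sigma"].reshape(-1),
    }
    for j, mid in enumerate(res.model.data.mouse_ids):
        cols[f"R_{mid}"] = res.draws["R"][:, :, j].reshape(-1)
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.17g")


def run_pipeline(config: RunConfig) -> CloneFractionResults:
    """Fit the hierarchical model per ``config`` and write a result bundle.

    The output directory receives: ``posterior_summary.txt``,
    ``draws.tsv`` (chain, draw, every sampled quantity),
    ``diagnostics.json``, ``resolved_config.yaml`` and ``run.log``.
    Non-convergence is a logged warning, not a failure.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        params = config.resolved_params()
        logger.info(
            "tissue constants: N=%d lam=%g/day tau=%g d (preset=%s)",
            params.N, params.lam, params.tau, config.preset,
        )
        table = load_cohort_table(config.input_table)
        if config.kind is not None:
            df = table.df.copy()
            df["kind"] = Observable.parse(config.kind).value
            table = CohortTable(df)
        logger.info("cohort: %d mice, %d crypts scored",
                    len(table), int(table.crypts.sum()))
        mcmc = dataclasses.replace(config.mcmc, seed=config.seed)
        model = CloneFractionModel(table, params, config.priors)
        res = model.fit(mcmc)
        if not res.converged:
            logger.warning("convergence criteria not met; see diagnostics")
        (outdir / "posterior_summary.txt").write_text(res.summary() + "\n")
        _write_draws_tsv(res, outdir / "draws.tsv")
        diag = {
            "converged": res.converged,
            "acceptance": res.acceptance,
            "rhat": {
                k: None if np.isnan(x) else x
                for k, x in res.summary_frame["rhat"].items()
            },
            "ess": {
                k: None if np.isnan(x) else x
                for k, x in res.summary_frame["ess"].items()
            },
        }
        (outdir / "diagnostics.json").write_text(json.dumps(diag, indent=2))
        (outdir / "resolved_config.yaml").write_text(
            yaml.safe_dump(config.to_mapping(), sort_keys=True)
        )
        logger.info("posterior median v = %.4f", res.median("v"))
        return res
    finally:
        logger.removeHandler(handler)
        handler.close()
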