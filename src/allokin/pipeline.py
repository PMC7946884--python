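"""End-to-end orchestration: simulate → CSP → CHESCA → CONCISE → thermo/kinetics.

The pipeline is driven by a :class:`PipelineConfig` (loadable from a YAML
file), runs every stage on either a synthetic dataset or user-supplied tables,
and writes plain CSV tables mirroring the standard presentation of the
analysis: the per-residue correlation-score profile, the community correlation
matrix, and the ⟨PC⟩ / %-closed / ΔΔG table.  Identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import chesca, concise, csp, kinetics, synthetic, thermo
from .errors import ConfigError
from .shift_io import CommunityMap, ShiftTable, read_community_map, read_shift_table

logger = logging.getLogger("allokin")

#: printed dissociation constants (μM) of the wild-type kinase and the
#: J-domain chimera used as default ITC simulation truths:
#: ATPγN binding, PKI binding to apo, PKI binding to the nucleotide-bound form.
DEFAULT_KDS = {
    "WT": {"ATPgN": 83.0, "PKI_apo": 17.0, "PKI_nuc": 0.16},
    "chimera": {"ATPgN": 19.0, "PKI_apo": 9.0, "PKI_nuc": 1.1},
}


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run."""

    # inputs: either paths or a synthetic config
    shift_table: str | None = None
    community_map: str | None = None
    synthetic: synthetic.SyntheticShiftConfig | None = None
    states: list[str] | None = None

    # analysis cutoffs
    chesca_cutoff: float = chesca.DEFAULT_CUTOFF
    community_cutoff: float = chesca.DEFAULT_COMMUNITY_CUTOFF
    csp_sd_multiplier: float = 1.0
    linearity_min: float = concise.DEFAULT_LINEARITY_MIN
    score_denominator: int | None = None

    # free-energy anchors
    ddg_closed: float = concise.DEFAULT_DDG_CLOSED
    temperature: float = thermo.DEFAULT_TEMPERATURE

    # ITC / kinetics simulation truths
    itc_kds: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_KDS.items()}
    )
    itc_dh: float = -10.0
    mm_vmax: float = 0.3
    mm_km: float = 40.0
    mm_enzyme_conc: float = 0.01
    mm_s_grid: list[float] = field(default_factory=lambda: [5, 10, 20, 40, 80, 160, 320])

    seed: int = 0
    outdir: str = "allokin_out"

    def __post_init__(self):
        for name in ("chesca_cutoff", "community_cutoff"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigError(f"{name} must lie in (0, 1]")
        if self.shift_table is None and self.synthetic is None:
            self.synthetic = synthetic.SyntheticShiftConfig(seed=self.seed)
        for path in (self.shift_table, self.community_map):
            if path is not None and not Path(path).exists():
                raise ConfigError(f"input file not found: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = synthetic.SyntheticShiftConfig(**raw["synthetic"])
        return cls(**raw)


def _setup_logging(outdir: Path) -> None:
    handlers = [logging.StreamHandler(sys.stderr),
                logging.FileHandler(outdir / "run.log", mode="w")]
    fmt = logging.Formatter("%(levelname)s %(name)s: %(message)s")
    root = logging.getLogger("allokin")
    root.setLevel(logging.INFO)
    for h in list(root.handlers):
        root.removeHandler(h)
    for h in handlers:
        h.setFormatter(fmt)
        root.addHandler(h)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage and write the report bundle to ``config.outdir``.

    Returns a dict of in-memory results keyed by stage name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    logger.info("config: %s", config)

    bundle: dict[str, Any] = {}

    # --- input stage -------------------------------------------------------
    truth = None
    if config.shift_table is not None:
        table = read_shift_table(config.shift_table, states=config.states)
        cmap = (read_community_map(config.community_map)
                if config.community_map else CommunityMap())
    else:
        table, cmap, truth = synthetic.generate_shift_dataset(config.synthetic)
        table.write(outdir / "shifts.csv")
        cmap.write(outdir / "communities.csv")
        truth.to_json(outdir / "ground_truth.json")
    states = config.states or table.states
    if any(s not in table.states for s in states):
        raise ConfigError(
            f"unknown state label(s): {[s for s in states if s not in table.states]}"
        )
    bundle["table"], bundle["communities"], bundle["truth"] = table, cmap, truth

    # --- CSP: apo vs ternary ----------------------------------------------
    profile = csp.csp_profile(table, states[0], states[-1],
                              sd_multiplier=config.csp_sd_multiplier)
    csp_df = csp.profile_frame(profile)
    csp_df.to_csv(outdir / "csp.csv", index=False)
    bundle["csp"] = profile

    # --- CHESCA -------------------------------------------------------------
    responsive = chesca.filter_responsive_residues(table, states)
    matrix = chesca.correlation_matrix(table, responsive, states,
                                       cutoff=config.chesca_cutoff)
    matrix.to_frame().to_csv(outdir / "chesca_matrix.csv")
    scores = chesca.correlation_scores(matrix, denominator=config.score_denominator)
    scores.to_frame().to_csv(outdir / "chesca_scores.csv", index=False)
    clusters = chesca.cluster_residues(matrix)
    pd.DataFrame(sorted(clusters.items()), columns=["residue_id", "cluster"]).to_csv(
        outdir / "chesca_clusters.csv", index=False)
    bundle["chesca_matrix"], bundle["chesca_scores"] = matrix, scores
    bundle["clusters"] = clusters
    if len(cmap):
        community_m = chesca.community_correlation(matrix, cmap,
                                                   r_cutoff=config.community_cutoff)
        community_m.R.to_csv(outdir / "community_matrix.csv")
        bundle["community_matrix"] = community_m

    # --- CONCISE ------------------------------------------------------------
    result = concise.concise_scores(table, states, linearity_min=config.linearity_min)
    result.scores.to_csv(outdir / "concise_scores.csv")
    dens = pd.DataFrame({
        "state": result.states,
        "mean_pc": [result.mean_pc[s] for s in result.states],
        "sd_pc": [result.sd_pc[s] for s in result.states],
    })
    dens.to_csv(outdir / "concise_densities.csv", index=False)
    fmap = concise.free_energy_map(result, ddg_closed=config.ddg_closed)
    fmap.to_frame().to_csv(outdir / "free_energy.csv", index=False)
    bundle["concise"], bundle["free_energy"] = result, fmap
    if len(cmap):
        bundle["community_concise"] = concise.community_concise(table, cmap, states)

    # --- ITC / cooperativity -------------------------------------------------
    itc_rows, sigma = [], {}
    for enzyme, kds in config.itc_kds.items():
        fits = {}
        for ligand, kd in kds.items():
            iso = synthetic.generate_itc_isotherm(
                kd=kd, dh=config.itc_dh, seed=config.seed,
                temperature=config.temperature)
            fit = thermo.fit_isotherm(iso)
            dec = thermo.decompose(fit.kd, fit.dh, config.temperature)
            fits[ligand] = fit
            itc_rows.append({
                "enzyme": enzyme, "ligand": ligand, "true_kd_uM": kd,
                "fit_kd_uM": fit.kd, "dG_kcal_mol": dec.dG,
                "dH_kcal_mol": dec.dH, "TdS_kcal_mol": dec.TdS,
            })
        if {"PKI_apo", "PKI_nuc"} <= set(fits):
            sigma[enzyme] = thermo.cooperativity_sigma(
                fits["PKI_apo"].kd, fits["PKI_nuc"].kd)
    pd.DataFrame(itc_rows).to_csv(outdir / "itc_fits.csv", index=False)
    bundle["itc"], bundle["sigma"] = itc_rows, sigma
    if {"WT", "chimera"} <= set(sigma):
        ratio, fold = thermo.fold_change(sigma["WT"].sigma, sigma["chimera"].sigma)
        bundle["sigma_fold_loss"] = (ratio, fold)
        logger.info("cooperativity fold-loss: %.2f (%d-fold)", ratio, fold)

    # --- kinetics -------------------------------------------------------------
    vdata = synthetic.generate_mm_dataset(
        config.mm_vmax, config.mm_km, config.mm_s_grid, seed=config.seed,
        enzyme_conc=config.mm_enzyme_conc)
    mmfit = kinetics.fit_mm(vdata)
    eff = kinetics.catalytic_efficiency(mmfit, config.mm_enzyme_conc)
    pd.DataFrame([{
        "vmax_uM_s": mmfit.vmax, "vmax_se": mmfit.vmax_se,
        "km_uM": mmfit.km, "km_se": mmfit.km_se,
        "kcat_per_s": eff.kcat, "kcat_km_per_uM_s": eff.efficiency,
        "kcat_km_se": eff.efficiency_se,
    }]).to_csv(outdir / "mm_fit.csv", index=False)
    bundle["mm"], bundle["efficiency"] = mmfit, eff

    # --- summary -------------------------------------------------------------
    summary = {
        "n_residues": len(table.residues),
        "n_responsive": len(responsive),
        "mean_correlation_score": float(pd.Series(scores.scores).mean()),
        "mean_pc": result.mean_pc,
        "percent_closed": fmap.percent_closed,
        "ddg_kcal_mol": fmap.ddg,
        "sigma": {k: v.sigma for k, v in sigma.items()},
    }
    if "sigma_fold_loss" in bundle:
        summary["sigma_fold_loss"] = bundle["sigma_fold_loss"][0]
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    bundle["summary"] = summary
    logger.info("pipeline complete; outputs in %s", outdir)
    return bundle
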