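"""End-to-end orchestration: simulate → Hill → I-V → gating → cycles.

Every stage reads the previous stage's files, so a run directory is a
self-contained record; the report carries the SHA-256 hash of the
canonical config so identical configs yield byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io
from .constants import GATE_POSITIONS, WT_RESIDUE
from .datatypes import Measurement, MutantSpec, ValidationError, annotate_mutant
from .hill import fit_hill
from .mwc import (
    ConductanceLevels,
    fit_chemical_global,
    fit_mutant_deltaG,
    subconductance_ratios,
)
from .cycles import analyze_pair, triple_coupling, one_sample_t
from .permeation import PermeationParams, fit_iv, predict_single_occupancy_iv
from .synthetic import (
    SimulationScenario,
    generate_dose_response_panel,
    generate_iv,
    hydration_specs,
    triad_specs,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "fit_hill", "fit_iv", "fit_gating", "cycles")

#: default double-mutant cycles (valine single steps) and the triple cycle
DEFAULT_PAIRS = ((550, 551), (550, 641), (551, 641))


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    out_dir: str
    seed: int = 0
    l2_wt: float = 10.0
    stages: tuple[str, ...] = ALL_STAGES
    scenario: dict = field(default_factory=dict)  # SimulationScenario overrides
    iv_params: dict = field(default_factory=dict)  # mutant_id -> condition -> params
    pairs: tuple[tuple[int, int], ...] = DEFAULT_PAIRS
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValidationError(f"unknown stage(s): {sorted(unknown)}")
        if self.l2_wt <= 0:
            raise ValidationError("l2_wt must be positive")
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ValidationError("seed must be a non-negative integer")
        for pair in self.pairs:
            if not set(pair) <= set(GATE_POSITIONS):
                raise ValidationError(f"cycle pair {pair} outside gate positions")
        self.pairs = tuple(tuple(p) for p in self.pairs)
        self.stages = tuple(self.stages)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = io.load_json(path)
        if "pairs" in raw:
            raw["pairs"] = tuple(tuple(p) for p in raw["pairs"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def canonical(self) -> str:
        """Canonical JSON of the scientific configuration; excludes fields
        (output path, verbosity) that do not affect the computation."""
        payload = asdict(self)
        payload.pop("out_dir", None)
        payload.pop("log_level", None)
        return json.dumps(payload, sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()

    def build_scenario(self) -> SimulationScenario:
        kwargs = dict(self.scenario)
        kwargs.setdefault("seed", self.seed)
        kwargs.setdefault("l2_wt", self.l2_wt)
        if "coupling" in kwargs:
            kwargs["coupling"] = {
                tuple(int(x) for x in k.split("-")): v
                for k, v in kwargs["coupling"].items()
            }
        if "levels" in kwargs:
            kwargs["levels"] = {
                mid: (v if isinstance(v, ConductanceLevels)
                      else ConductanceLevels(*v))
                for mid, v in kwargs["levels"].items()
            }
        return SimulationScenario(**kwargs)


def _vline_spec(positions: tuple[int, ...]) -> MutantSpec:
    """Construct with Val at the given positions, Ile elsewhere."""
    res = tuple(
        "V" if pos in positions else WT_RESIDUE for pos in GATE_POSITIONS
    )
    return MutantSpec(residues=res)


def _measure(fit, name: str) -> Measurement:
    return Measurement(fit.param(name), fit.se_of(name))


def _cycles_from_gating(gating: dict, pairs) -> dict:
    """Double- and triple-mutant cycle couplings from fitted ΔG_mut values.

    Cycle corners are the valine-substitution constructs of each pair,
    built in the wild-type background and in the background where the
    third gate residue is itself mutated to Val; the difference of the two
    couplings is the triadic term.  The t-test dof is the most
    conservative (smallest) dof among the contributing corner fits.
    """

    def corner(spec: MutantSpec) -> tuple[Measurement, int]:
        entry = gating["dg_mut"][spec.mutant_id]
        p = entry["parameters"]["dg_mut"]
        return Measurement(p["value"], p["se"]), entry["dof"]

    cycle_report: dict = {"pairs": [], "triples": []}
    couplings: dict = {}
    for pair in pairs:
        for background in (None, *sorted(set(GATE_POSITIONS) - set(pair))):
            bg = () if background is None else (background,)
            corners, dofs = {}, []
            for key, extra in (
                ("wt", ()), ("x", (pair[0],)), ("y", (pair[1],)), ("xy", pair)
            ):
                m, dof = corner(_vline_spec(tuple(bg) + tuple(extra)))
                corners[key] = m
                dofs.append(dof)
            result = analyze_pair(
                tuple(str(p) for p in pair), corners, dof=min(dofs),
                background=("WT" if not bg else _vline_spec(bg).mutant_id),
            )
            cycle_report["pairs"].append(result.to_dict())
            couplings[(tuple(pair), bg)] = (result.coupling, min(dofs))
    for pair in pairs:
        third = tuple(sorted(set(GATE_POSITIONS) - set(pair)))
        base, dof_b = couplings[(tuple(pair), ())]
        mutated, dof_m = couplings[(tuple(pair), third)]
        quad = triple_coupling(base, mutated)
        test = one_sample_t(quad.value, quad.se, min(dof_b, dof_m))
        cycle_report["triples"].append({
            "pair": [str(p) for p in pair],
            "third": str(third[0]),
            "dddd_g_kcal_mol": quad.value,
            "se": quad.se,
            "t": test.t, "p": test.p, "significant": test.significant,
        })
    return cycle_report


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order.

    Returns the run report (also written to ``report.json``).  A stage
    whose inputs are missing is recorded as skipped; per-mutant failures
    inside a stage do not abort the others.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    curves_path = out / "curves.csv"
    iv_path = out / "iv.csv"

    if "simulate" in config.stages:
        scenario = config.build_scenario()
        rng = scenario.rng()
        methyl_specs = triad_specs()
        hyd_specs = [s for s in hydration_specs() if not s.is_wt]
        curves_me, truth = generate_dose_response_panel(
            scenario, panel=methyl_specs, series="methyl", rng=rng
        )
        curves_hy, truth_hy = generate_dose_response_panel(
            scenario, panel=hyd_specs, series="hydration", rng=rng
        )
        truth["mutants"].update(truth_hy["mutants"])
        io.save_dose_response(curves_me + curves_hy, curves_path)
        mutants = {s.mutant_id: s for s in methyl_specs + hyd_specs}
        io.save_mutants(mutants, out / "mutants.json")
        iv_curves = []
        for mutant_id, by_cond in sorted(config.iv_params.items()):
            for condition, raw in sorted(by_cond.items()):
                params = PermeationParams(**raw)
                iv_curves.append(
                    generate_iv(scenario, params, condition,
                                mutant_id=mutant_id, rng=rng)
                )
        if iv_curves:
            io.save_iv(iv_curves, iv_path)
        io.save_json(truth, out / "truth.json")
        report["stages"]["simulate"] = {
            "n_curves": len(curves_me) + len(curves_hy),
            "n_iv": len(iv_curves),
        }

    if "fit_hill" in config.stages:
        curves = io.load_dose_response(curves_path)
        hill: dict = {}
        for curve in curves:
            entry: dict = {}
            if curve.basal is not None:
                entry["basal"] = curve.basal
            try:
                params, fit = fit_hill(curve)
            except Exception as exc:  # per-mutant isolation
                logger.warning("Hill fit failed for %s: %s", curve.mutant_id, exc)
                entry["error"] = str(exc)
            else:
                entry.update(ec50=params.ec50, h=params.h, fit=fit.to_dict())
            hill[curve.mutant_id] = entry
        io.save_json(hill, out / "hill.json")
        report["stages"]["fit_hill"] = {
            "n_fitted": sum("ec50" in e for e in hill.values())
        }

    levels_by_mutant: dict[str, ConductanceLevels] = {}
    if "fit_iv" in config.stages:
        if iv_path.exists():
            iv_curves = io.load_iv(iv_path)
            grouped: dict[str, dict] = {}
            for c in iv_curves:
                grouped.setdefault(c.mutant_id, {})[c.condition] = c
            perm: dict = {}
            for mid, by_cond in sorted(grouped.items()):
                entry: dict = {}
                fits: dict = {}
                for cond, curve in sorted(by_cond.items()):
                    params, fit = fit_iv(curve)
                    fits[cond] = params
                    entry[cond] = {
                        "A": params.A, "sigma_h": params.sigma_h,
                        "sigma_beta": params.sigma_beta, "fit": fit.to_dict(),
                    }
                if {"zero_ca", "saturating_ca"} <= fits.keys():
                    single_curve, _ = predict_single_occupancy_iv(
                        fits["zero_ca"], fits["saturating_ca"],
                        by_cond["saturating_ca"].voltages,
                    )
                    lev = subconductance_ratios(
                        by_cond["zero_ca"], by_cond["saturating_ca"], single_curve
                    )
                    levels_by_mutant[mid] = lev
                    entry["levels"] = {
                        "i_over_k": lev.i_over_k, "j_over_k": lev.j_over_k,
                    }
                perm[mid] = entry
            io.save_json(perm, out / "perm.json")
            report["stages"]["fit_iv"] = {"n_mutants": len(perm)}
        else:
            logger.warning(
                "no iv.csv found; gating will use i/k = j/k = 0 defaults"
            )
            report["stages"]["fit_iv"] = {"skipped": "no I-V data"}

    if "fit_gating" in config.stages:
        curves = io.load_dose_response(curves_path)
        mutants = io.load_mutants(out / "mutants.json")
        hill = io.load_json(out / "hill.json")
        methyl_ids = {s.mutant_id for s in triad_specs()}
        default_lev = ConductanceLevels(0.0, 0.0)
        methyl_series, hydration_series = [], []
        lev_me, lev_hy = [], []
        for mid, entry in hill.items():
            if "ec50" not in entry or mid not in mutants:
                continue
            lev = levels_by_mutant.get(mid, default_lev)
            if mid in methyl_ids:
                pert = annotate_mutant(mutants[mid])
                methyl_series.append((pert.delta_n_me, entry["ec50"]))
                lev_me.append(lev)
            else:
                pert = annotate_mutant(mutants[mid], require_methyl=False)
                hydration_series.append((pert.ddg_hydration, entry["ec50"]))
                lev_hy.append(lev)
        chem = fit_chemical_global(
            methyl_series, hydration_series, l2_wt=config.l2_wt,
            levels_methyl=lev_me, levels_hydration=lev_hy, seed=config.seed,
        )
        dg_fits = fit_mutant_deltaG(
            [c for c in curves if c.mutant_id in methyl_ids],
            kd_c=chem.kd_c, kd_o=chem.kd_o, l2_wt=config.l2_wt,
            levels_by_mutant=levels_by_mutant,
        )
        gating = {
            "chemical": {
                "dg_me": chem.dg_me, "delta": chem.delta,
                "kd_c": chem.kd_c, "kd_o": chem.kd_o,
                "fit": chem.fit.to_dict(),
            },
            "dg_mut": {
                mid: (fit.to_dict() if fit is not None else None)
                for mid, fit in sorted(dg_fits.items())
            },
        }
        io.save_json(gating, out / "gating.json")
        report["stages"]["fit_gating"] = {
            "dg_me": chem.dg_me, "delta": chem.delta,
            "n_mutants": len(dg_fits),
        }

    if "cycles" in config.stages:
        gating = io.load_json(out / "gating.json")
        cycle_report = _cycles_from_gating(gating, config.pairs)
        io.save_json(cycle_report, out / "cycles.json")
        report["stages"]["cycles"] = {
            "n_pairs": len(cycle_report["pairs"]),
            "n_triples": len(cycle_report["triples"]),
        }

    io.save_json(report, out / "report.json")
    return report
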