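"""End-to-end orchestration: scenarios -> (images) -> records -> statistics.

Two execution paths cover the same biology at different cost:

* the *model-only* path evaluates the damage model's true mean % tail DNA
  per condition and simulates replicate-well medians around it — fast
  enough for whole screens in seconds;
* the *imaging* path renders synthetic CometChip fields per well, registers
  the microwell grid, segments every comet and aggregates per-well medians
  through the same statistics.

Because a single screen's verdict pattern is a draw from 18 significance
families, the pattern-level API (:func:`consensus_screen`) repeats the
simulated experiment and reports the modal verdict per chemical and arm,
the in-silico analogue of repeating an experiment before tabulating it.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import presets as pz
from .calibration import GAMMA_DOSE_DESIGN_GY, StandardCurve, fit_standard_curve
from .model import (
    AgentPreset,
    DamageScenario,
    DEFAULT_PARAMS,
    ModelParams,
    ValidationError,
    scenario_tail_pct,
    viability as model_viability,
)
from .quant import qc_filter, quantify_field
from .screen_stats import (
    ConditionSummary,
    DunnettOutcome,
    ScreenCall,
    call_genotoxicity,
    dunnett_vs_control,
    summarize_condition,
)
from .synth import make_condition_images

__all__ = [
    "RunConfig",
    "ScreenResult",
    "model_only_evaluate",
    "simulate_condition_medians",
    "simulate_screen",
    "consensus_screen",
    "simulate_calibration_curve",
    "run_experiment",
]

logger = logging.getLogger("hepacomet")

ARMS = ("no_inhibitor", "hu_arac")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one simulated experiment."""

    mode: str = "screen"  # screen | calibrate | simulate
    cell_line: str = "HepaRG"
    chemicals: Tuple[str, ...] = tuple(pz.SCREEN_PANEL)
    arms: Tuple[str, ...] = ARMS
    n_wells: int = 3
    time_h: float = 1.0
    alpha: float = 0.05
    viability_threshold: Optional[float] = None
    sigma_well: float = 2.0  # percentage points, model-only path
    seed: int = 0
    imaging: bool = False
    grid_shape: Tuple[int, int] = (8, 6)
    occupancy: float = 0.9
    kappa: float = 60.0
    well_sd: float = 1.0
    min_comets: int = 100
    outdir: str = "results"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.n_wells < 1:
            raise ValidationError("n_wells must be >= 1")

    def config_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("chemicals", "arms", "grid_shape"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def model_only_evaluate(
    scenario: DamageScenario,
    preset: Optional[AgentPreset] = None,
    params: ModelParams = DEFAULT_PARAMS,
) -> float:
    """Shortcut path: damage model -> tail transform, no imaging."""
    if preset is None:
        preset = pz.agent_preset(scenario.agent)
    return scenario_tail_pct(scenario, preset, params)


def simulate_condition_medians(
    scenario: DamageScenario,
    n_wells: int,
    sigma_well: float,
    rng: np.random.Generator,
    preset: Optional[AgentPreset] = None,
    params: ModelParams = DEFAULT_PARAMS,
) -> np.ndarray:
    """Model-only replicate-well medians: Normal jitter around the model
    truth, truncated to the metric's range."""
    truth = model_only_evaluate(scenario, preset, params)
    return np.clip(rng.normal(truth, sigma_well, size=n_wells), 0.0, 100.0)


@dataclass
class ScreenResult:
    calls: List[ScreenCall]
    summaries: pd.DataFrame  # one row per condition
    config: RunConfig

    def calls_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chemical": [c.chemical for c in self.calls],
                "arm": [c.arm for c in self.calls],
                "verdict": [c.verdict for c in self.calls],
                "dose_range": [c.dose_range for c in self.calls],
                "excluded_doses": [
                    ";".join(f"{d:g}" for d in c.excluded_doses) for c in self.calls
                ],
            }
        )

    def report_text(self) -> str:
        lines = [
            f"Genotoxicity screen ({self.config.cell_line}, "
            f"alpha={self.config.alpha}, "
            f"viability threshold="
            f"{self.config.viability_threshold if self.config.viability_threshold is not None else 'off'})",
            "",
            f"{'chemical':<18}{'arm':<14}{'verdict':<9}{'significant doses'}",
        ]
        for c in self.calls:
            extra = f"  (excluded: {c.excluded_doses})" if c.excluded_doses else ""
            lines.append(f"{c.chemical:<18}{c.arm:<14}{c.verdict:<9}{c.dose_range}{extra}")
        return "\n".join(lines)


def _condition_wells(
    config: RunConfig,
    scenario: DamageScenario,
    preset: AgentPreset,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, int, bool]:
    """(well medians, n clean comets, qc pass) for one condition."""
    if not config.imaging:
        med = simulate_condition_medians(
            scenario, config.n_wells, config.sigma_well, rng, preset
        )
        # the model-only path has no comet-count attrition
        return med, config.n_wells * 10**3, True
    fields = make_condition_images(
        scenario,
        preset,
        n_wells=config.n_wells,
        grid_shape=config.grid_shape,
        occupancy=config.occupancy,
        kappa=config.kappa,
        well_sd=config.well_sd,
        seed=int(rng.integers(2**31 - 1)),
    )
    frames = []
    for well, (fld, _manifest) in enumerate(fields):
        rec = quantify_field(fld, field_id=well)
        rec["well"] = well
        frames.append(rec)
    records = pd.concat(frames, ignore_index=True)
    records["condition"] = scenario.label
    clean, status = qc_filter(records, min_comets=config.min_comets)
    n_clean = int(status["n_clean"].iloc[0])
    if not bool(status["qc_pass"].iloc[0]):
        return np.array([]), n_clean, False
    med = clean.groupby("well")["percent_tail"].median().to_numpy()
    return med, n_clean, True


def simulate_screen(
    config: RunConfig, seed: Optional[int] = None
) -> ScreenResult:
    """One full simulated screen under ``config`` (single experiment)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    calls: List[ScreenCall] = []
    rows = []
    for chem in config.chemicals:
        preset = pz.agent_preset(chem)
        doses = pz.screen_doses(chem)
        for arm in config.arms:
            hu = arm == "hu_arac"
            vehicle = pz.make_scenario(
                chem, 0.0, config.time_h, config.cell_line, hu_arac=hu,
                vehicle=True, label=f"{chem}|{arm}|vehicle",
            )
            conds = [vehicle] + [
                pz.make_scenario(
                    chem, d, config.time_h, config.cell_line, hu_arac=hu,
                    label=f"{chem}|{arm}|{d:g}",
                )
                for d in doses
            ]
            wells: List[np.ndarray] = []
            ok = True
            for sc in conds:
                med, n_clean, qc_ok = _condition_wells(config, sc, preset, rng)
                ok = ok and qc_ok
                wells.append(med)
                via = model_viability(sc, preset)
                summ = (
                    ConditionSummary.from_well_values(
                        sc.label, med, n_comets=n_clean, viability=via, qc_pass=qc_ok
                    )
                    if med.size
                    else None
                )
                rows.append(
                    {
                        "chemical": chem,
                        "arm": arm,
                        "dose": sc.dose,
                        "mean_tail": summ.mean if summ else float("nan"),
                        "sem_tail": summ.sem if summ else float("nan"),
                        "n_wells": med.size,
                        "n_comets": n_clean,
                        "viability": via,
                        "qc_pass": qc_ok,
                    }
                )
            if not ok:
                logger.warning("%s/%s failed the comet-count QC gate", chem, arm)
                calls.append(
                    ScreenCall(chemical=chem, arm=arm, verdict="-", dose_range="QC fail")
                )
                continue
            outcome = dunnett_vs_control(
                wells[0], wells[1:], alpha=config.alpha, alternative="greater", rng=rng
            )
            via_map = {
                d: model_viability(sc, preset) for d, sc in zip(doses, conds[1:])
            }
            calls.append(
                call_genotoxicity(
                    chem,
                    arm,
                    doses,
                    outcome,
                    viability=via_map,
                    viability_threshold=config.viability_threshold,
                    dose_unit=preset.dose_unit,
                )
            )
    return ScreenResult(calls=calls, summaries=pd.DataFrame(rows), config=config)


def consensus_screen(
    config: RunConfig, n_reps: int = 5, seed: Optional[int] = None
) -> pd.DataFrame:
    """Modal verdict per (chemical, arm) over ``n_reps`` replicate screens."""
    base = config.seed if seed is None else seed
    ss = np.random.SeedSequence(base)
    verdicts: Dict[Tuple[str, str], List[str]] = {}
    for child in ss.spawn(n_reps):
        rep_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        res = simulate_screen(config, seed=rep_seed)
        for c in res.calls:
            verdicts.setdefault((c.chemical, c.arm), []).append(c.verdict)
    rows = []
    for (chem, arm), vs in verdicts.items():
        pos = vs.count("+")
        rows.append(
            {
                "chemical": chem,
                "arm": arm,
                "verdict": "+" if pos * 2 > len(vs) else "-",
                "positive_reps": pos,
                "n_reps": len(vs),
            }
        )
    return pd.DataFrame(rows)


def simulate_calibration_curve(
    cell_line: str = "TK6",
    doses_gy: Sequence[float] = tuple(GAMMA_DOSE_DESIGN_GY),
    n_wells: int = 3,
    sigma_well: float = 1.0,
    seed: int = 0,
    imaging: bool = False,
    config: Optional[RunConfig] = None,
) -> StandardCurve:
    """Simulate the gamma dose ladder and fit the standard curve.

    Irradiation is scored immediately (repair time 0), as on ice.
    """
    cfg = config or RunConfig(
        mode="calibrate", cell_line=cell_line, n_wells=n_wells,
        sigma_well=sigma_well, seed=seed, imaging=imaging,
    )
    rng = np.random.default_rng(cfg.seed)
    preset = pz.agent_preset("gamma")
    means = []
    for d in doses_gy:
        sc = pz.make_scenario(
            "gamma", d, time_h=0.0, cell_line_name=cell_line,
            vehicle=(d == 0), label=f"gamma|{d:g}Gy",
        )
        med, _, qc_ok = _condition_wells(cfg, sc, preset, rng)
        if not qc_ok:
            raise ValidationError(f"gamma dose {d} Gy failed the QC gate")
        means.append(float(np.mean(med)))
    return fit_standard_curve(list(doses_gy), means, cell_model=cell_line)


def run_experiment(config: RunConfig, outdir: Optional[str | Path] = None) -> Dict[str, Path]:
    """Run the configured experiment and write the result bundle.

    Outputs carry the config hash and seed; deterministic stages are
    byte-identical across reruns of the same config.
    Returns a name -> path map of everything written.
    """
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    written: Dict[str, Path] = {}

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("config hash %s seed %d mode %s", chash, config.seed, config.mode)
        cfg_path = out / "config.yaml"
        cfg_payload = asdict(config)
        cfg_payload["config_hash"] = chash
        cfg_path.write_text(yaml.safe_dump(cfg_payload, sort_keys=True))
        written["config"] = cfg_path

        if config.mode == "calibrate":
            curve = simulate_calibration_curve(
                cell_line=config.cell_line, n_wells=config.n_wells,
                sigma_well=config.sigma_well, seed=config.seed,
                imaging=config.imaging, config=config,
            )
            path = out / "standard_curve.csv"
            curve.to_frame().to_csv(path, index=False)
            written["standard_curve"] = path
            logger.info(
                "standard curve: slope %.1f SSB per point, R2 %.4f", curve.slope, curve.r_squared
            )
        else:
            result = simulate_screen(config)
            p1 = out / "screen_calls.csv"
            result.calls_frame().to_csv(p1, index=False)
            p2 = out / "condition_summaries.csv"
            result.summaries.to_csv(p2, index=False)
            p3 = out / "screen_report.txt"
            p3.write_text(result.report_text() + "\n")
            written.update(screen_calls=p1, condition_summaries=p2, screen_report=p3)
            n_pos = sum(c.verdict == "+" for c in result.calls)
            logger.info("screen finished: %d/%d positive calls", n_pos, len(result.calls))
    finally:
        logger.removeHandler(handler)
        handler.close()
    return written
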