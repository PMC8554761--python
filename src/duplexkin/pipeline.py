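"""End-to-end pipeline: simulate -> featurize -> slow modes -> microstates
-> MSM -> macrostates -> mechanism -> thermodynamic comparison.

Every stage writes its artifacts into the run directory; the summary
collects macrostate count, populations, implied timescales, MFPTs, pathway
fractions and the free-energy table, together with the master seed and a
hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import constants as C
from . import featurize as feat
from . import mechanism, msm, slow_modes, thermo_nn
from .duplex_synth import build_preset, simulate_equilibrium

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "label_macrostates"]

SHIFTED_LABELS = ("5S2", "3S2", "5S4", "3S4")


@dataclass
class PipelineConfig:
    """Validated end-to-end run configuration (units nm / ns)."""

    sequence: str = "AT-all"
    n_frames: int = 500_000
    n_traj: int = 40
    dt_save: float = 0.6
    u: float = 0.0
    seed: int = 0
    epsilon: float = feat.DEFAULT_EPSILON
    lag: float = 1.2
    n_modes: int = 5
    k_micro: int = 200
    gap_ratio: float = 3.0
    bound_cutoff: float = C.BOUND_CUTOFF
    dissoc_cutoff: float = C.DISSOC_CUTOFF
    n_boot: int = 100
    temperature_K: float = 310.0
    outdir: str | None = None

    def validate(self) -> None:
        if self.sequence not in C.PRESET_SEQUENCES:
            raise ValueError(
                f"unknown sequence {self.sequence!r}; choose from "
                f"{sorted(C.PRESET_SEQUENCES)}"
            )
        if self.n_frames < 1 or self.n_traj < 1:
            raise ValueError("n_frames and n_traj must be positive")
        if self.dt_save <= 0 or self.lag <= 0 or self.epsilon <= 0:
            raise ValueError("dt_save, lag and epsilon must be positive")
        steps = self.lag / self.dt_save
        if abs(steps - round(steps)) > 1e-9 or round(steps) < 1:
            raise ValueError("lag must be a positive multiple of dt_save")
        if self.n_frames // self.n_traj <= self.lag / self.dt_save:
            raise ValueError("trajectories shorter than the lag")
        if not 0 < self.bound_cutoff < self.dissoc_cutoff:
            raise ValueError("require 0 < bound_cutoff < dissoc_cutoff")
        if self.k_micro < 2 or self.n_modes < 1:
            raise ValueError("k_micro >= 2 and n_modes >= 1 required")

    def content_hash(self) -> str:
        payload = json.dumps(
            {k: v for k, v in asdict(self).items() if k != "outdir"},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    n_macrostates: int
    macro_labels: list
    pi_macro: np.ndarray
    implied_timescales: np.ndarray
    micro_msm: msm.ReversibleMSM
    macro_model: msm.MacrostateModel
    thermo: pd.DataFrame | None
    pathway: mechanism.PathwayReport | None
    summary: dict
    truth_agreement: float | None = None
    geometric_labels: list = field(default_factory=list)
    assignment: msm.MicrostateAssignment | None = None


def label_macrostates(
    macro_model: msm.MacrostateModel,
    assignment: msm.MicrostateAssignment,
    geo_labels: list,
) -> list:
    """Name macrostates by the majority geometric label of their frames.

    ``geo_labels`` holds per-trajectory arrays of classifier labels; each
    crisp macrostate is named after the most common geometric label among
    its frames (excluding the unassigned sentinel).
    """
    proj = np.full(assignment.k, -1, dtype=np.int64)
    proj[macro_model.active_set] = macro_model.crisp
    macro_of_frame = np.concatenate([proj[t] for t in assignment.labels])
    geo = np.concatenate([np.asarray(g, dtype=object) for g in geo_labels])
    names = []
    for m in range(macro_model.n_macro):
        sel = macro_of_frame == m
        vals, cnts = np.unique(
            geo[sel][geo[sel] != mechanism.UNASSIGNED].astype(str),
            return_counts=True,
        )
        names.append(str(vals[np.argmax(cnts)]) if len(vals) else "?")
    return names


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages; returns the in-memory result and writes artifacts.

    Identical configurations (and hence identical content hashes) produce
    identical outputs.
    """
    config.validate()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        logger.info("stage %s (config %s, seed %d)", name,
                    config.content_hash(), config.seed)

    preset = build_preset(config.sequence).with_temperature(config.u)
    sequence = preset.sequence

    # --- simulate + featurize + classify, one trajectory at a time -------
    _stage("simulate/featurize")
    per_traj = config.n_frames // config.n_traj
    features, truth, geo_labels = [], [], []
    ss = np.random.SeedSequence(config.seed)
    for i, child in enumerate(ss.spawn(config.n_traj)):
        traj = simulate_equilibrium(
            preset, per_traj, config.dt_save,
            seed=int(child.generate_state(1)[0] % (2 ** 31)),
        )
        dm = feat.distance_matrices(traj.frames)
        features.append(
            feat.symmetrized_reciprocal_features(dm, config.epsilon)
            .astype(np.float32)
        )
        geo_labels.append(
            mechanism.classify_frames(
                dm, sequence, config.bound_cutoff, config.dissoc_cutoff
            )
        )
        truth.append(traj.truth_labels)
        del traj, dm

    # --- slow modes ------------------------------------------------------
    _stage("slow_modes")
    model = slow_modes.fit_linear_slow_modes(
        features, lag=config.lag, n_modes=config.n_modes,
        dt_save=config.dt_save,
    )
    embedding = model.transform(features)
    del features

    # --- microstates and MSM --------------------------------------------
    _stage("msm")
    assignment = msm.cluster_microstates(
        embedding, k=config.k_micro, seed=config.seed,
        dt_save=config.dt_save,
    )
    micro = msm.estimate_reversible_msm(assignment, lag=config.lag)
    n_macro = msm.select_n_macrostates(micro, gap_ratio=config.gap_ratio)
    macro = msm.pcca_coarse_grain(micro, n_macro, assignment=assignment)
    names = label_macrostates(macro, assignment, geo_labels)

    # --- truth agreement (diagnostic only) -------------------------------
    proj = np.full(assignment.k, -1, dtype=np.int64)
    proj[macro.active_set] = macro.crisp
    macro_names = np.array(names, dtype=object)
    predicted = []
    for t in assignment.labels:
        p = proj[t]
        lab = np.where(p >= 0, macro_names[np.clip(p, 0, None)], "?")
        predicted.append(lab)
    pred = np.concatenate(predicted)
    tru = np.concatenate(truth)
    truth_agreement = float((pred == tru).mean())

    # --- mechanism -------------------------------------------------------
    _stage("mechanism")
    pathway = None
    if "D" in names and "H" in names:
        d_idx = [names.index("D")]
        h_idx = [names.index("H")]
        via_sets = {
            "shifted": [i for i, s in enumerate(names) if s in SHIFTED_LABELS],
            "F4": [i for i, s in enumerate(names) if s == "F4"],
        }
        pathway = mechanism.pathway_report(macro, d_idx, h_idx, via_sets)

    # --- thermodynamics --------------------------------------------------
    _stage("thermo")
    pi_by_name = {}
    for name, p in zip(names, macro.pi_macro):
        pi_by_name[name] = pi_by_name.get(name, 0.0) + float(p)
    thermo = None
    if "H" in pi_by_name:
        thermo = thermo_nn.macrostate_thermo_table(
            sequence, pi_by_name, config.temperature_K
        )

    summary = {
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_macrostates": n_macro,
        "macro_labels": names,
        "pi_macro": [float(p) for p in macro.pi_macro],
        "pi_by_label": pi_by_name,
        "shifted_occupancy_percent": 100.0 * sum(
            v for k_, v in pi_by_name.items() if k_ in SHIFTED_LABELS
        ),
        "implied_timescales_ns": [
            float(t) for t in micro.implied_timescales[:10]
        ],
        "discarded_frame_fraction": micro.discarded_frame_fraction,
        "truth_agreement": truth_agreement,
        "mfpt_ns": (
            {
                "D->H": mechanism.mfpt(
                    macro, config.lag, [names.index("D")], [names.index("H")]
                ),
                "H->D": mechanism.mfpt(
                    macro, config.lag, [names.index("H")], [names.index("D")]
                ),
            } if "D" in names and "H" in names else {}
        ),
        "fraction_via": (
            {k_: float(v) for k_, v in pathway.fraction_via.items()}
            if pathway else {}
        ),
    }

    if outdir:
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True)
        )
        pd.DataFrame({
            "macrostate": names,
            "pi": macro.pi_macro,
        }).to_csv(outdir / "populations.tsv", sep="\t", index=False)
        pd.DataFrame(
            macro.P, index=names, columns=names
        ).to_csv(outdir / "macro_transition_matrix.tsv", sep="\t")
        pd.DataFrame({
            "implied_timescale_ns": micro.implied_timescales[:20]
        }).to_csv(outdir / "implied_timescales.tsv", sep="\t", index=False)
        if thermo is not None:
            thermo.to_csv(outdir / "thermo_msm_vs_nn.tsv", sep="\t",
                          index=False)
        if pathway is not None:
            pd.DataFrame(
                pathway.mfpt_matrix, index=names, columns=names
            ).to_csv(outdir / "mfpt_matrix_ns.tsv", sep="\t")
            report = pd.DataFrame({
                "macrostate": names,
                "committor_D_to_H": pathway.qplus,
            })
            for key, frac in pathway.fraction_via.items():
                report[f"fraction_via_{key}"] = frac
            report.to_csv(outdir / "pathway_report.tsv", sep="\t",
                          index=False)

    return PipelineResult(
        config=config,
        n_macrostates=n_macro,
        macro_labels=names,
        pi_macro=macro.pi_macro,
        implied_timescales=micro.implied_timescales,
        micro_msm=micro,
        macro_model=macro,
        thermo=thermo,
        pathway=pathway,
        summary=summary,
        truth_agreement=truth_agreement,
        geometric_labels=geo_labels,
        assignment=assignment,
    )
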