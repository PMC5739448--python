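"""End-to-end analysis bundle: linearize, decompose, dominate, dissect.

``run_report`` chains the whole pipeline on one model and reference state
and returns a JSON-serializable bundle plus pandas tables.  Every random
choice is derived from the single ``seed``, so a rerun with the same seed
reproduces the bundle byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dominance import (
    all_diagonal_fractions,
    attribute_diagonal,
    gershgorin_discs,
    half_reaction_ratios,
)
from .dynamics import integrate, perturb_atp
from .modal import classify_dominance_modes, eigendecompose
from .network import KineticState, ReactionNetwork, build_jacobian
from .powerit import deflate_until_timescale
from .synthetic import find_steady_state


@dataclass
class ReportBundle:
    bundle: dict
    dominance_table: pd.DataFrame
    half_reaction_table: pd.DataFrame
    mode_table: pd.DataFrame


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, complex):
        return {"re": obj.real, "im": obj.imag}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, float) and not np.isfinite(obj):
        return repr(obj)
    return obj


def run_report(
    network: ReactionNetwork,
    state: KineticState | None = None,
    cutoff: float = 0.05,
    seed: int = 0,
    top_k: int = 3,
    perturb: bool = False,
    perturb_delta: float = 0.1,
    solve_steady: bool = False,
    outdir: str | Path | None = None,
) -> ReportBundle:
    """Run the full modal-structure analysis on one model.

    Stages: steady-state check (optionally relaxing the given state to
    steady state first) -> G and J with term attribution -> modal
    decomposition -> per-row dominance and Gershgorin discs -> half-reaction
    equilibrium table -> explained/complex classification -> deflation walk
    covering the ``top_k`` fastest complex modes -> optional ATP-hydrolysis
    perturbation simulation.  Failures carry their stage name.
    """
    stage = "state"
    try:
        if state is None or solve_steady:
            x0 = state.x if state is not None else None
            if x0 is None:
                raise ValueError("no reference state given")
            state = find_steady_state(network, x0)
        stage = "linearization"
        lin = build_jacobian(network, state)
        stage = "modal decomposition"
        dec = eigendecompose(lin.J, species=network.species)
        stage = "dominance analysis"
        fs = all_diagonal_fractions(lin.J)
        discs = gershgorin_discs(lin.J, dec.eigenvalues, species=network.species)
        attribution = [attribute_diagonal(lin, i) for i in range(network.n_species)]
        stage = "half reactions"
        halves = half_reaction_ratios(network, state)
        stage = "mode classification"
        modes, summary = classify_dominance_modes(dec, lin.J, cutoff=cutoff)
        stage = "power-iteration dissection"
        complex_modes = [m for m in modes if m.classification == "complex"]
        complex_modes.sort(key=lambda m: -abs(m.eigenvalue.real))
        dissection = []
        if complex_modes:
            targets = complex_modes[:top_k]
            slowest = min(abs(m.eigenvalue.real) for m in targets)
            walk = deflate_until_timescale(
                lin.J, target_timescale=1.0 / slowest * 0.999, seed=seed
            )
            for step in walk.steps:
                support = np.nonzero(
                    np.abs(step.u) >= cutoff * np.abs(step.u).max()
                )[0]
                dissection.append(
                    {
                        "eigenvalue_estimate": step.eigenvalue,
                        "magnitude": step.magnitude,
                        "timescale": step.timescale,
                        "residual_vs_original": step.residual_vs_original,
                        "support": [network.species[i] for i in support],
                    }
                )
        stage = "perturbation"
        perturbation = None
        if perturb:
            kicked = perturb_atp(network, state, delta=perturb_delta)
            finite = [t for t in dec.timescales if np.isfinite(t) and t > 0]
            t_end = 10.0 * max(finite) if finite else 1.0
            traj = integrate(network, kicked, t_end=t_end)
            perturbation = {
                "delta": perturb_delta,
                "t_end": t_end,
                "final_residual": float(
                    np.linalg.norm(network.time_derivatives(traj.final))
                ),
            }
    except Exception as exc:
        raise RuntimeError(f"report failed in stage '{stage}': {exc}") from exc

    dominance_table = pd.DataFrame(
        {
            "species": network.species,
            "center": [d.center for d in discs],
            "radius": [d.radius for d in discs],
            "diagonal_fraction": fs,
            "strong": [d.strong for d in discs],
            "attributed_reaction": [a.reaction_id for a in attribution],
            "attributed_g_value": [a.g_value for a in attribution],
            "attribution_share": [a.share for a in attribution],
        }
    )
    half_reaction_table = pd.DataFrame(
        {
            "reaction": [h.reaction_id for h in halves],
            "fixed_species": [h.fixed_species or "" for h in halves],
            "k_d": [h.k_d for h in halves],
            "ratio": [h.ratio for h in halves],
            "classification": [h.classification for h in halves],
            "gamma": [h.gamma for h in halves],
            "k_eq": [h.k_eq for h in halves],
        }
    )
    mode_table = pd.DataFrame(
        {
            "mode": [m.index for m in modes],
            "eigenvalue_re": [m.eigenvalue.real for m in modes],
            "eigenvalue_im": [m.eigenvalue.imag for m in modes],
            "timescale": [m.timescale for m in modes],
            "classification": [m.classification for m in modes],
            "support": ["|".join(m.support_names()) for m in modes],
        }
    )
    bundle = {
        "model": network.name,
        "version": __version__,
        "seed": seed,
        "units": network.units,
        "n_species": network.n_species,
        "n_reactions": network.n_reactions,
        "steady_state": {
            "residual": state.residual,
            "is_steady": bool(state.is_steady),
            "tolerance": state.tolerance,
        },
        "mode_summary": {
            "explained": summary.explained,
            "complex": summary.complex,
            "conservation": summary.conservation,
            "explained_percentage": summary.explained_percentage,
            "explained_percentage_including_conservation": (
                summary.explained_percentage_including_conservation
            ),
            "counting_convention": (
                "percentages exclude conservation (lambda=0) modes; the "
                "inclusive tally is reported alongside"
            ),
        },
        "dominance": dominance_table.to_dict(orient="records"),
        "half_reactions": half_reaction_table.to_dict(orient="records"),
        "modes": mode_table.to_dict(orient="records"),
        "dissection": dissection,
        "perturbation": perturbation,
        "truncation_cutoff": cutoff,
    }
    bundle = _jsonify(bundle)
    out = ReportBundle(
        bundle=bundle,
        dominance_table=dominance_table,
        half_reaction_table=half_reaction_table,
        mode_table=mode_table,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(bundle, indent=2) + "\n")
        dominance_table.to_csv(outdir / "dominance.csv", index=False)
        half_reaction_table.to_csv(outdir / "half_reactions.csv", index=False)
        mode_table.to_csv(outdir / "modes.csv", index=False)
    return out
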