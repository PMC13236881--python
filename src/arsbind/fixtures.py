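"""Worked synthetic dataset bundle for demos, tests and the CLI.

Everything written here is simulated or constructed — including the FASTA
records, which are synthetic stand-ins shaped like small metalloregulator
sequences (cysteine positions chosen to exercise the annotator), not real
protein sequences.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .datasets import LoadingDataset
from .io import (
    fasta_text,
    write_competition,
    write_isotherm,
    write_kinetics,
    write_loading,
    write_report,
    write_suspensions,
)
from .particles import AdsorbentSuspension
from .simulate import (
    BindingParams,
    CompetitiveParams,
    NoiseModel,
    default_isotherm_design,
    simulate_competitive_series,
    simulate_isotherm,
    simulate_kinetics,
)

#: Reference suspension: 1.00 g/L at 1.657e11 particles/g (2.75e-7 μM).
REFERENCE_SUSPENSION = AdsorbentSuspension(
    mass_conc=1.00, particles_per_gram=1.657e11, label="S")

#: Flagship binding parameters: K_A 30.49 μM^-1, 2.80e7 sites per particle.
REFERENCE_BINDING = BindingParams(
    ka=30.49, sites_per_particle=2.80e7, suspension=REFERENCE_SUSPENSION)


def _synthetic_sequences() -> dict[str, str]:
    """Synthetic amino-acid sequences with controlled cysteine placement."""
    def with_cys(length: int, positions: tuple[int, ...]) -> str:
        body = ("MKTLDALSERFQVLAHPVRLAILELLAQGE" * 5)[:length]
        chars = [c if c != "C" else "S" for c in body]
        for p in positions:
            chars[p - 1] = "C"
        return "".join(chars)

    return {
        "synthetic_repressor_5C": with_cys(117, (91, 92, 99, 109, 110)),
        "synthetic_repressor_3C": with_cys(105, (32, 34, 37)),
        "synthetic_repressor_0C": with_cys(98, ()),
    }


def write_fixture_bundle(outdir: str | Path, seed: int) -> dict[str, Path]:
    """Write a complete worked dataset bundle under ``outdir``; return the paths.

    The bundle covers every table schema the analysis modules read: suspension
    metadata, a triplicate noisy isotherm, a pseudo-second-order time course,
    a competitive series with equal affinities, a loading series with a
    saturated tail, an interference table, and a synthetic protein FASTA.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731
    paths: dict[str, Path] = {}

    paths["suspensions"] = out / "suspensions.csv"
    write_suspensions({"S": REFERENCE_SUSPENSION}, paths["suspensions"])

    iso = simulate_isotherm(
        REFERENCE_BINDING, default_isotherm_design(REFERENCE_BINDING),
        noise=NoiseModel(seed=sub()), replicates=3, label="S-conjugate")
    paths["isotherm"] = out / "isotherm.csv"
    write_isotherm(iso, paths["isotherm"])

    kin = simulate_kinetics(
        "PSO", q_e=74.07, k=0.01964, times=np.arange(0.5, 12.5, 0.5),
        noise=NoiseModel(cv=0.02, seed=sub()), label="S-conjugate")
    paths["kinetics"] = out / "kinetics.csv"
    write_kinetics(kin, paths["kinetics"])

    capacity = REFERENCE_BINDING.capacity
    comp = simulate_competitive_series(
        CompetitiveParams(kd1=1 / 30.49, kd2=1 / 30.49,
                          r_total=capacity, p_total=7.85),
        np.linspace(0.8, 7.2, 8), noise=NoiseModel(cv=0.02, seed=sub()))
    paths["competition"] = out / "competition.csv"
    write_competition(comp, paths["competition"])

    # Loading: exactly linear below saturation, flat plateau above.
    slope = 2.733e7
    protein_total = 2.157
    sphere = np.concatenate([np.linspace(0.05e-7, 0.7e-7, 6),
                             [2.0e-7, 2.7e-7, 3.4e-7]])
    bound = np.minimum(slope * sphere, 0.93 * protein_total)
    paths["loading"] = out / "loading.csv"
    write_loading(LoadingDataset(sphere_conc=sphere, protein_bound=bound,
                                 protein_total=protein_total, label="conjugate"),
                  paths["loading"])

    retention_pct = {"S": 78.7, "conjugate-1": 99.2, "conjugate-2": 99.6,
                     "conjugate-8": 94.5}
    rows = [{"adsorbent": label, "metal": "Cu", "Q_with": 100.0 * pct / 100.0,
             "Q_without": 100.0} for label, pct in retention_pct.items()]
    paths["interference"] = out / "interference.csv"
    write_report(rows, paths["interference"])

    paths["fasta"] = out / "synthetic_sequences.fasta"
    paths["fasta"].write_text(fasta_text(_synthetic_sequences()))
    return paths
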