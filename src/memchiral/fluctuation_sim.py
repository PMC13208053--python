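"""Gaussian residue-fluctuation simulation and RMSF/RMSD profiles.

This is not molecular dynamics: each residue is assigned a noise amplitude
drawn uniformly from a configured band, every frame displaces each atom of
the residue by independent per-axis Gaussian noise of that amplitude, and
the resulting per-residue RMSF and per-atom RMSD profiles resemble
early-stage fluctuation profiles. Chain termini get a configurable amplitude
boost (peripheral residues are more mobile). A single seed governs all
draws; results are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import StructureModel


@dataclass
class FlexConfig:
    """Parameters of the fluctuation simulation.

    amp_min/amp_max bound the per-residue, per-axis noise SD in Angstroms;
    residues within ``terminal_window`` of either end of a protein chain get
    their amplitude multiplied by ``terminal_boost``.
    """

    n_frames: int = 100
    amp_min: float = 0.8
    amp_max: float = 1.2
    terminal_boost: float = 1.0
    terminal_window: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.amp_min <= self.amp_max):
            raise ValueError("need 0 <= amp_min <= amp_max")
        if self.n_frames < 2:
            raise ValueError("insufficient frames: n_frames must be >= 2")
        if self.terminal_boost < 1.0:
            raise ValueError("terminal_boost must be >= 1")


@dataclass
class FlexResult:
    """Per-residue RMSF, per-atom RMSD profile, and the amplitudes used."""

    residues: list[tuple[str, int]]       # (chain, residue_seq), file order
    per_residue_rmsf: np.ndarray          # A, aligned with residues
    per_atom_rmsd_profile: np.ndarray     # A, atom file order
    amplitudes: np.ndarray                # A, aligned with residues


def _residue_groups(model: StructureModel):
    """Residues in file order with their atom indices."""
    order: list[tuple[str, int]] = []
    groups: dict[tuple[str, int], list[int]] = {}
    for i, a in enumerate(model.atoms):
        key = (a.chain_id, a.residue_seq)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(i)
    return order, groups


def simulate_fluctuations(model: StructureModel,
                          cfg: FlexConfig) -> FlexResult:
    """Run the Gaussian-noise simulation and compute RMSF/RMSD profiles.

    RMSF of residue j is the root of the mean (over frames and the residue's
    atoms) squared deviation of the displaced position from that atom's
    frame-mean position; with a constant amplitude a it converges to a*sqrt(3)
    as n_frames grows (three independent axes). The per-atom RMSD profile
    measures deviation from the input reference coordinates instead.
    """
    if not model.atoms:
        raise ValueError("model has no residues")
    cfg.__post_init__()  # re-validate in case fields were mutated
    rng = np.random.default_rng(cfg.seed)
    order, groups = _residue_groups(model)

    # chain position of each residue, for the terminal boost
    chain_res: dict[str, list[tuple[str, int]]] = {}
    for key in order:
        chain_res.setdefault(key[0], []).append(key)
    amps = np.empty(len(order))
    for j, key in enumerate(order):
        a = rng.uniform(cfg.amp_min, cfg.amp_max)
        seq = chain_res[key[0]]
        pos = seq.index(key)
        is_protein = any(model.component_of.get(i) == "protein"
                         for i in groups[key]) if model.component_of else True
        if (cfg.terminal_window > 0 and is_protein
                and (pos < cfg.terminal_window
                     or pos >= len(seq) - cfg.terminal_window)):
            a *= cfg.terminal_boost
        amps[j] = a

    n_atoms = len(model.atoms)
    atom_amp = np.empty(n_atoms)
    for j, key in enumerate(order):
        for i in groups[key]:
            atom_amp[i] = amps[j]

    # streaming accumulation: per-axis sums/sumsqs of displacement
    s = np.zeros((n_atoms, 3))
    ss = np.zeros((n_atoms, 3))
    rmsd_acc = np.zeros(n_atoms)
    for _ in range(cfg.n_frames):
        disp = rng.normal(0.0, 1.0, size=(n_atoms, 3)) * atom_amp[:, None]
        s += disp
        ss += disp ** 2
        rmsd_acc += (disp ** 2).sum(axis=1)
    f = cfg.n_frames
    per_axis_var = ss / f - (s / f) ** 2            # deviation from frame mean
    per_atom_msf = per_axis_var.sum(axis=1)
    rmsf = np.array([np.sqrt(np.mean(per_atom_msf[groups[key]]))
                     for key in order])
    rmsd_profile = np.sqrt(rmsd_acc / f)
    return FlexResult(residues=order, per_residue_rmsf=rmsf,
                      per_atom_rmsd_profile=rmsd_profile, amplitudes=amps)


def rmsd_pair(cloud_a, cloud_b) -> float:
    """Root-mean-square deviation between two equally sized ordered clouds.

    No superposition is performed: coordinates are compared as given.
    """
    a = np.asarray(cloud_a.coords if hasattr(cloud_a, "coords") else cloud_a,
                   dtype=float)
    b = np.asarray(cloud_b.coords if hasattr(cloud_b, "coords") else cloud_b,
                   dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch between clouds")
    return float(np.sqrt(np.mean(((a - b) ** 2).sum(axis=1))))


class GaussianFluctuationSimulator:
    """Estimator wrapper around :func:`simulate_fluctuations`.

    ``fit(model)`` runs the simulation and exposes ``result_``,
    ``rmsf_range_`` (min, max per-residue RMSF) and ``median_rmsf_``.
    """

    def __init__(self, n_frames: int = 100, amp_min: float = 0.8,
                 amp_max: float = 1.2, terminal_boost: float = 1.0,
                 terminal_window: int = 0, seed: int = 0):
        self.n_frames = n_frames
        self.amp_min = amp_min
        self.amp_max = amp_max
        self.terminal_boost = terminal_boost
        self.terminal_window = terminal_window
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("n_frames", "amp_min", "amp_max", "terminal_boost",
                 "terminal_window", "seed")}

    def set_params(self, **params) -> "GaussianFluctuationSimulator":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X: StructureModel, y=None) -> "GaussianFluctuationSimulator":
        cfg = FlexConfig(**self.get_params())
        self.result_ = simulate_fluctuations(X, cfg)
        rmsf = self.result_.per_residue_rmsf
        self.rmsf_range_ = (float(rmsf.min()), float(rmsf.max()))
        self.median_rmsf_ = float(np.median(rmsf))
        return self
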