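"""Export of the learned γ as a coarse-grained simulation pair potential.

The sequence-specific protein-DNA term attaches a tanh well to each
amino-acid/phosphate pair,

    V_PD(r) = (W/2)·(1 + tanh(η(r₀ − r))),

with r₀ = 8 Å, η = 0.7 Å⁻¹ and W the learned γ normalized so Σ|W| = 1
(signs preserved). Companion terms are a Debye-Hückel screened Coulomb
interaction (dielectric ε = 78.0) and a (σ/r)¹² excluded-volume wall
(σ = 4.0 Å). Gap-optimized γ carries no absolute energy scale, so the
kcal/mol prefactor applied to W is an explicit user parameter.

Tables are written per amino-acid/nucleotide pair as whitespace-separated
(r, E, −dE/dr) columns with analytic forces and a self-describing header.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .alphabets import AA_ALPHABET, NT_NAMES
from .optimize import EnergyModel

#: Coulomb constant 1/(4πε₀) in kcal·Å/(mol·e²).
COULOMB_KCAL = 332.0636


@dataclass
class PairPotentialParams:
    """Parameters of the exported sequence-specific pair potential."""

    W: np.ndarray                  # 20x4, Σ|W| = 1
    r0: float = 8.0                # Å, tanh well midpoint
    eta: float = 0.7               # Å⁻¹, tanh steepness
    dielectric: float = 78.0
    debye_length: float = 10.0     # Å
    sigma: float = 4.0             # Å, excluded-volume radius
    eps_scale: float = 1.0         # excluded-volume well-depth scale
    energy_scale: float = 1.0      # kcal/mol prefactor applied to W
    attach_site: str = "P"         # DNA site the tanh term attaches to
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        if abs(np.abs(self.W).sum() - 1.0) > 1e-12:
            raise ValueError("W must be normalized so that sum(|W|) == 1")
        for name in ("r0", "eta", "debye_length", "sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def normalize_gamma(model: EnergyModel) -> np.ndarray:
    """W = γ / Σ|γ|; signs preserved, Σ|W| = 1."""
    total = np.abs(model.gamma).sum()
    if total == 0:
        raise ValueError("gamma is all zero")
    return model.gamma / total


def v_pd(r, w_an: float, r0: float = 8.0, eta: float = 0.7):
    """Sequence-specific tanh well: (w/2)·(1 + tanh(η(r₀ − r)))."""
    r = np.asarray(r, dtype=float)
    out = 0.5 * w_an * (1.0 + np.tanh(eta * (r0 - r)))
    return float(out) if out.ndim == 0 else out


def v_pd_force(r, w_an: float, r0: float = 8.0, eta: float = 0.7):
    """−dV_PD/dr = (w/2)·η·sech²(η(r₀ − r))."""
    r = np.asarray(r, dtype=float)
    out = 0.5 * w_an * eta / np.cosh(eta * (r0 - r)) ** 2
    return float(out) if out.ndim == 0 else out


def u_elec(r, qi: float, qj: float, l_d: float, dielectric: float = 78.0):
    """Debye-Hückel screened Coulomb energy (kcal/mol; charges in e, r in Å)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive for the electrostatic term")
    out = COULOMB_KCAL * qi * qj / (dielectric * r) * np.exp(-r / l_d)
    return float(out) if out.ndim == 0 else out


def u_elec_force(r, qi: float, qj: float, l_d: float, dielectric: float = 78.0):
    """−dU_elec/dr = U_elec·(1/r + 1/l_D)."""
    e = u_elec(r, qi, qj, l_d, dielectric)
    r = np.asarray(r, dtype=float)
    out = e * (1.0 / r + 1.0 / l_d)
    return float(out) if np.ndim(out) == 0 else out


def u_exclude(r, sigma: float = 4.0, eps_scale: float = 1.0):
    """Excluded-volume wall 4ε(σ/r)¹²."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive for the excluded-volume term")
    out = 4.0 * eps_scale * (sigma / r) ** 12
    return float(out) if out.ndim == 0 else out


def u_exclude_force(r, sigma: float = 4.0, eps_scale: float = 1.0):
    """−dU_exclude/dr = 48ε σ¹²/r¹³ = 12·U_exclude/r."""
    r = np.asarray(r, dtype=float)
    out = 12.0 * u_exclude(r, sigma, eps_scale) / r
    return float(out) if np.ndim(out) == 0 else out


def params_from_model(model: EnergyModel, energy_scale: float = 1.0,
                      debye_length: float = 10.0, **kwargs) -> PairPotentialParams:
    return PairPotentialParams(
        W=normalize_gamma(model), energy_scale=energy_scale,
        debye_length=debye_length,
        provenance={"gamma_provenance": model.provenance,
                    "n_modes": model.n_modes, **model.metadata},
        **kwargs)


def export_tables(params: PairPotentialParams, out_dir,
                  r_min: float = 0.5, r_cut: float = 20.0,
                  spacing: float = 0.05) -> dict:
    """Write one (r, E, −dE/dr) table per amino-acid/nucleotide pair.

    The sequence-specific table energy is ``energy_scale·W(a,n)`` times the
    tanh well; companion unit-charge electrostatic and excluded-volume
    tables are exported once. Forces are analytic. Returns the manifest.
    """
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    if r_min <= 0:
        raise ValueError("grid must exclude r = 0 "
                         "(electrostatic and excluded terms diverge)")
    os.makedirs(out_dir, exist_ok=True)
    n = int(round((r_cut - r_min) / spacing)) + 1
    r = r_min + spacing * np.arange(n)

    def header(title, extra=""):
        return ("# {t}\n# r0={p.r0} eta={p.eta} dielectric={p.dielectric} "
                "lD={p.debye_length} sigma={p.sigma} eps_scale={p.eps_scale} "
                "energy_scale={p.energy_scale} attach_site={p.attach_site}\n"
                "# provenance: {prov}\n{extra}"
                "# columns: r[A] energy[kcal/mol] force[kcal/mol/A]\n").format(
            t=title, p=params, prov=json.dumps(params.provenance), extra=extra)

    manifest = {"r_min": r_min, "r_cut": r_cut, "spacing": spacing,
                "n_points": n, "files": {}}
    for i, aa in enumerate(AA_ALPHABET):
        for j, nt in enumerate(NT_NAMES):
            w = params.energy_scale * params.W[i, j]
            e = v_pd(r, w, params.r0, params.eta)
            f = v_pd_force(r, w, params.r0, params.eta)
            name = f"vpd_{aa}_{nt}.table"
            _write_table(os.path.join(out_dir, name),
                         header(f"sequence-specific tanh term {aa}-{nt}",
                                f"# W={params.W[i, j]:.12g}\n"), r, e, f)
            manifest["files"][f"{aa}-{nt}"] = name

    e = u_elec(r, 1.0, 1.0, params.debye_length, params.dielectric)
    f = u_elec_force(r, 1.0, 1.0, params.debye_length, params.dielectric)
    _write_table(os.path.join(out_dir, "elec_unit_charge.table"),
                 header("Debye-Hückel term, unit charges"), r, e, f)
    manifest["files"]["elec"] = "elec_unit_charge.table"

    e = u_exclude(r, params.sigma, params.eps_scale)
    f = u_exclude_force(r, params.sigma, params.eps_scale)
    _write_table(os.path.join(out_dir, "excluded_volume.table"),
                 header("excluded-volume wall"), r, e, f)
    manifest["files"]["exclude"] = "excluded_volume.table"

    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _write_table(path, header: str, r, e, f) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        for ri, ei, fi in zip(r, np.broadcast_to(e, r.shape),
                              np.broadcast_to(f, r.shape)):
            fh.write(f"{ri:.17g} {ei:.17g} {fi:.17g}\n")


def read_table(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Parse an exported table back into (r, energy, force) arrays."""
    data = np.loadtxt(path, comments="#")
    return data[:, 0], data[:, 1], data[:, 2]
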