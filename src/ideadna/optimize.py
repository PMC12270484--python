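"""Learning the amino-acid × nucleotide interaction energy matrix γ.

The binding energy of a threaded sequence pair is linear in its contact
features, E = Σ_{a,n} γ(a,n) φ(a,n), with lower E meaning stronger predicted
binding. Training maximizes the gap-to-variance ratio δE/ΔE between native
(strong) binders and randomized decoys:

    δE = Aᵀγ,  ΔE = √(γᵀBγ),
    A  = ⟨φ_decoy⟩ − ⟨φ_strong⟩,
    B  = ⟨φ_decoy φ_decoyᵀ⟩ − ⟨φ_decoy⟩⟨φ_decoyᵀ⟩,

whose maximizer is γ ∝ B⁻¹A. Finite decoy sampling makes the small
eigenmodes of B noisy, so B is eigendecomposed and all eigenvalues beyond
the leading ``n_modes`` are replaced by the ``n_modes``-th before inversion.
The overall energy scale is undetermined (reduced units); γ is normalized to
unit Euclidean norm with the sign fixed so decoys score higher than strong
binders.

When quantitative affinities are available (SELEX-style tables), γ can
instead be fit by ridge regression of ΔΔG = RT·ln(ΔKd) on φ.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Ridge

from .alphabets import AA_ALPHABET, N_FEATURES, NT_NAMES
from .featurize import DEFAULT_SWITCH, SwitchParams, compute_phi, thread_dna
from .structio import CoarseGrainedComplex, InterfaceSelection

logger = logging.getLogger(__name__)

#: Gas constant in kcal/(mol·K).
R_KCAL = 1.98720425e-3
DEFAULT_TEMPERATURE = 298.15
#: Relative eigenvalue tolerance: modes below tol·λ_max count as zero.
EIGEN_TOL = 1e-12


def _as_matrix(phis) -> np.ndarray:
    arr = np.asarray(phis, dtype=float)
    if arr.ndim == 3:  # stack of 20x4 matrices
        arr = arr.reshape(arr.shape[0], -1)
    elif arr.ndim == 2 and arr.shape == (N_FEATURES // 4, 4):
        arr = arr.reshape(1, -1)
    return arr


@dataclass
class GapStatistics:
    """First/second-moment statistics of the strong-vs-decoy energy gap."""

    A: np.ndarray          # (d,) mean decoy features minus mean strong features
    B: np.ndarray          # (d, d) population covariance of decoy features
    n_strong: int
    n_decoy: int


def compute_gap_statistics(strong_phis, decoy_phis) -> GapStatistics:
    """A and B from stacks of φ vectors (population covariance over decoys)."""
    strong = _as_matrix(strong_phis)
    decoy = _as_matrix(decoy_phis)
    if len(strong) < 1:
        raise ValueError("need at least one strong binder")
    if len(decoy) < 2:
        raise ValueError("need at least two decoys (covariance undefined)")
    A = decoy.mean(axis=0) - strong.mean(axis=0)
    centered = decoy - decoy.mean(axis=0)
    B = centered.T @ centered / len(decoy)
    B = 0.5 * (B + B.T)
    return GapStatistics(A=A, B=B, n_strong=len(strong), n_decoy=len(decoy))


@dataclass
class EnergyModel:
    """Learned 20×4 interaction energy matrix in reduced units."""

    gamma: np.ndarray
    n_modes: int | None = None
    provenance: str = "gap-optimized"   # or "selex-ridge"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.gamma.size != N_FEATURES:
            raise ValueError(f"gamma must have {N_FEATURES} entries")
        self.gamma = self.gamma.reshape(N_FEATURES // 4, 4)
        if not np.all(np.isfinite(self.gamma)):
            raise ValueError("gamma entries must be finite")

    @property
    def vector(self) -> np.ndarray:
        return self.gamma.ravel()


def solve_gamma(stats: GapStatistics, n_modes: int | None = None) -> EnergyModel:
    """γ ∝ (eigen-filtered B)⁻¹ A, unit-normalized, oriented so δE > 0.

    ``n_modes=None`` keeps min(70, rank(B)) leading modes; an explicit
    ``n_modes`` whose eigenvalue is at tolerance raises (insufficient decoy
    diversity).
    """
    d = len(stats.A)
    evals, evecs = np.linalg.eigh(stats.B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int(np.sum(evals > EIGEN_TOL * max(evals[0], 0.0)))
    if rank == 0:
        raise ValueError("insufficient decoy diversity: B has no positive eigenvalues")

    if n_modes is None:
        n_modes = min(70, rank)
    if not 1 <= n_modes <= d:
        raise ValueError(f"n_modes must be in [1, {d}]")
    if n_modes > rank:
        raise ValueError(
            f"insufficient decoy diversity: eigenvalue {n_modes} of B is at "
            f"numerical zero (rank {rank})")

    filtered = evals.copy()
    filtered[n_modes:] = evals[n_modes - 1]
    gamma = evecs @ ((evecs.T @ stats.A) / filtered)
    if stats.A @ gamma < 0:
        gamma = -gamma
    norm = np.linalg.norm(gamma)
    if norm == 0:
        raise ValueError("degenerate statistics: A is orthogonal to all modes")
    gamma /= norm
    return EnergyModel(gamma=gamma, n_modes=int(n_modes),
                       metadata={"n_strong": stats.n_strong,
                                 "n_decoy": stats.n_decoy,
                                 "rank_B": rank})


def predict_energy(model: EnergyModel, phi) -> float:
    """E = Σ γ(a,n)·φ(a,n) in reduced units (lower = stronger binding)."""
    phi = np.asarray(phi, dtype=float)
    if phi.size != model.gamma.size:
        raise ValueError(f"phi has {phi.size} entries, expected {model.gamma.size}")
    return float(model.vector @ phi.ravel())


def energy_gap_ratio(gamma, stats: GapStatistics) -> float:
    """δE/ΔE = Aᵀγ / √(γᵀBγ), the training objective."""
    g = np.asarray(gamma, dtype=float).ravel()
    var = g @ stats.B @ g
    if var <= 0:
        raise ValueError("gamma has zero decoy-energy variance")
    return float(stats.A @ g / np.sqrt(var))


def ddg_from_kd(kd_ratio: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """ΔΔG = RT·ln(ΔKd) in kcal/mol for a dimensionless Kd ratio."""
    kd_ratio = np.asarray(kd_ratio, dtype=float)
    if np.any(kd_ratio <= 0):
        raise ValueError("Kd ratio must be positive")
    out = R_KCAL * temperature * np.log(kd_ratio)
    return float(out) if out.ndim == 0 else out


def kd_from_ddg(ddg: float, temperature: float = DEFAULT_TEMPERATURE):
    """Inverse of :func:`ddg_from_kd`."""
    return np.exp(np.asarray(ddg, dtype=float) / (R_KCAL * temperature))


def fit_gamma_selex(phi_matrix: np.ndarray, ddg_vector: np.ndarray,
                    alpha: float = 0.01) -> EnergyModel:
    """Ridge fit γ̂ = argmin ‖Φγ − ΔΔG‖² + α‖γ‖² on threaded features."""
    phi = _as_matrix(phi_matrix)
    y = np.asarray(ddg_vector, dtype=float)
    if phi.ndim != 2 or len(phi) < 2:
        raise ValueError("need at least two sequences to fit")
    if len(phi) != len(y):
        raise ValueError("phi matrix and ddg vector lengths disagree")
    if not np.any(phi):
        raise ValueError("all-zero feature matrix")
    ridge = Ridge(alpha=alpha, fit_intercept=False, solver="cholesky")
    ridge.fit(phi, y)
    return EnergyModel(gamma=ridge.coef_, n_modes=None, provenance="selex-ridge",
                       metadata={"alpha": float(alpha), "n_sequences": len(y)})


def predict_target_energy(model: EnergyModel, cplx: CoarseGrainedComplex,
                          interface: InterfaceSelection, target_dna: str,
                          params: SwitchParams = DEFAULT_SWITCH,
                          orientation_known: bool = True,
                          protein_seq: str | None = None) -> tuple[float, str]:
    """Thread a target DNA sequence and score it; returns (energy, strand).

    With unknown orientation both strand threadings are scored and the
    stronger (lower-energy) one is reported.
    """
    protein_seq = protein_seq or cplx.protein_sequence
    result = thread_dna(cplx, interface, target_dna, orientation_known=orientation_known)
    scored = [(predict_energy(model, compute_phi(cplx, interface, protein_seq, seq, params)),
               strand)
              for strand, seq in result.candidates]
    return min(scored, key=lambda t: t[0])


# ---------------------------------------------------------------------------
# Serialization and rendering


def save_model(model: EnergyModel, tsv_path, json_path=None) -> None:
    """Write γ as a 20-row TSV (rows = amino acids, cols DA/DT/DC/DG)."""
    with open(tsv_path, "w") as fh:
        fh.write("aa\t" + "\t".join(NT_NAMES) + "\n")
        for i, aa in enumerate(AA_ALPHABET):
            fh.write(aa + "\t" + "\t".join(f"{v:.12g}" for v in model.gamma[i]) + "\n")
    if json_path is not None:
        meta = {"provenance": model.provenance, "n_modes": model.n_modes,
                **model.metadata}
        with open(json_path, "w") as fh:
            json.dump(meta, fh, indent=2, default=str)


def load_model(tsv_path, json_path=None) -> EnergyModel:
    gamma = np.zeros((len(AA_ALPHABET), len(NT_NAMES)))
    with open(tsv_path) as fh:
        header = fh.readline().split()
        if header[1:] != list(NT_NAMES):
            raise ValueError(f"unexpected model columns {header[1:]}")
        for line in fh:
            parts = line.split()
            gamma[AA_ALPHABET.index(parts[0])] = [float(v) for v in parts[1:]]
    meta, prov, n_modes = {}, "gap-optimized", None
    if json_path is not None:
        with open(json_path) as fh:
            meta = json.load(fh)
        prov = meta.pop("provenance", prov)
        n_modes = meta.pop("n_modes", None)
    return EnergyModel(gamma=gamma, n_modes=n_modes, provenance=prov, metadata=meta)


def plot_heatmap(model: EnergyModel, path) -> None:
    """Render γ as an amino-acid × nucleotide heatmap (blue = favorable)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 8))
    vmax = np.abs(model.gamma).max()
    im = ax.imshow(model.gamma, cmap="bwr", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(len(NT_NAMES)), NT_NAMES)
    ax.set_yticks(range(len(AA_ALPHABET)), list(AA_ALPHABET))
    ax.set_xlabel("nucleotide")
    ax.set_ylabel("amino acid")
    fig.colorbar(im, ax=ax, label="interaction energy (reduced units)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
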