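"""Model parameters, unit conversions, and the adhesion -> contact-energy rule.

The simulator works on a cubic lattice where one voxel has a 2 micron side
and one Monte Carlo step (MCS) corresponds to 30 seconds of real time.
Contact energies are derived from experimental adhesion measurements by
normalising to the cancer-cell/matrix adhesion score, inverting, and
multiplying by ten (stronger measured adhesion -> lower contact energy).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

# lattice kind codes used throughout the kernels
KIND_MEDIUM = 0  # matrix / medium voxel (cell id 0)
KIND_SCC = 1     # squamous-cell-carcinoma cell
KIND_CAF = 2     # cancer-associated fibroblast
KIND_AIR = 3     # frozen phase above an organotypic culture (cell id -1)

AIR_ID = -1

VOXEL_UM = 2.0      # microns per voxel side
MCS_SECONDS = 30.0  # seconds per Monte Carlo step
MCS_PER_DAY = int(round(24 * 3600 / MCS_SECONDS))  # 2880

DAY4_MCS = 4 * MCS_PER_DAY   # default timepoint for the invasion metric suite
DAY5_MCS = 5 * MCS_PER_DAY   # track invasion score timepoint
DAY7_MCS = 7 * MCS_PER_DAY   # front curvature timepoint

# experimental SCC-ECM adhesion score everything is normalised to
REFERENCE_ADHESION = 45.53


def contact_energy_from_adhesion(adhesion_measure: float, reference: float = REFERENCE_ADHESION) -> int:
    """Convert an experimental adhesion score into an integer contact energy.

    Scores are normalised to the reference SCC-ECM adhesion, inverted, and
    multiplied by 10, so that strong measured adhesion maps to a low contact
    energy (low interfacial cost = adhesive interface).

    Parameters
    ----------
    adhesion_measure
        Experimental adhesion score for the interface of interest (> 0).
    reference
        Experimental SCC-ECM adhesion score used for normalisation (> 0).
    """
    if adhesion_measure <= 0 or reference <= 0:
        raise ValueError("adhesion scores must be positive")
    return int(round(10.0 * reference / adhesion_measure))


def voxels_to_um3(voxels: float) -> float:
    """Cell volume in cubic microns for a voxel count."""
    return voxels * VOXEL_UM ** 3


def mcs_to_days(mcs: float) -> float:
    """Simulated days elapsed after a number of Monte Carlo steps."""
    return mcs * MCS_SECONDS / (24 * 3600)


def speed_voxels_per_mcs_to_um_per_min(v: float) -> float:
    """Convert a centroid speed from voxels/MCS to microns/minute."""
    return v * VOXEL_UM * 60.0 / MCS_SECONDS


@dataclass(frozen=True)
class SimParams:
    """Full parameter set for one simulation.

    Contact energies and rates default to the wild-type calibration of the
    A431/VCAF system.  ``lambda_volume``, ``lambda_surface``, ``temperature``,
    ``ecm_barrier`` and ``caf_repulsion_penalty`` are calibration constants of
    this implementation (tuned once so that the median-speed and
    median-volume calibration rows hold; see docs/methods.md).
    """

    # --- contact energies (per boundary-voxel pair, 26-neighbourhood) ---
    j_scc_ecm: float = 10.0        # SCC vs full-density matrix
    j_scc_ecm_zero: float = 40.0   # SCC vs fully degraded matrix
    j_scc_scc: float = 21.0
    j_scc_caf: float = 35.0
    j_caf_caf: float = 45.0
    j_caf_ecm: float = 15.0
    j_air_cell: float = 100.0      # prohibitive: gas-liquid interface

    # --- constraint strengths / fluctuation amplitude (calibration) ---
    lambda_volume: float = 1.0
    lambda_surface: float = 0.15
    temperature: float = 40.0
    copy_connectivity: int = 6     # 6 (faces) or 26 (faces+edges+corners)
    # taxis coupling: energy per aligned copy = gain x taxis scale; one
    # constant per cell type, each fixed by that type's speed calibration row
    scc_taxis_gain: float = 6.0
    caf_taxis_gain: float = 2.0

    # --- directed motility ---
    taxis_energy_scc: float = 13.0
    caf_taxis_min: float = 3.5
    caf_taxis_max: float = 21.0
    caf_taxis_range: float = 30.0      # voxels; SCC stimulation range
    caf_taxis_override: float | None = None  # fix the CAF taxis scale (calibration runs)
    caf_repulsion_range: float = 20.0  # voxels (~1.5 CAF widths)
    caf_repulsion_penalty: float = 15.0

    # --- ECM remodelling ---
    degradation_rate_caf: float = 0.0012   # multiplicative per MCS
    degradation_rate_scc: float = 0.0001
    pushing_rate_caf: float = 0.0140       # fraction displaced per MCS
    pushing_rate_scc: float = 0.0
    ecm_barrier: float = 20.0              # energy per unit residual density on entry
    ecm_entry_max_density: float = 0.75    # steric limit: denser voxels are impassable

    # --- growth and mitosis (SCC only) ---
    scc_initial_target_volume: float = 400.0
    scc_dividing_volume: float = 800.0
    caf_target_volume: float = 800.0
    caf_target_surface: float = 700.0
    mean_time_to_mitosis: float = 8640.0   # MCS (= 3 days)

    def __post_init__(self):
        for name in ("degradation_rate_caf", "degradation_rate_scc",
                     "pushing_rate_caf", "pushing_rate_scc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    # SCC target surface scales with target volume like the CAF calibration
    # point (700 faces at 800 voxels): S_t = k * V_t^(2/3).
    @property
    def scc_surface_coefficient(self) -> float:
        return self.caf_target_surface / self.caf_target_volume ** (2.0 / 3.0)

    def scc_target_surface(self, target_volume: float) -> float:
        return self.scc_surface_coefficient * target_volume ** (2.0 / 3.0)

    def with_multipliers(self, proteolysis: float = 1.0,
                         scc_scc_adhesion: float = 1.0,
                         scc_ecm_adhesion: float = 1.0,
                         caf_degradation: float = 1.0,
                         caf_pushing: float = 1.0,
                         taxis: float = 1.0,
                         growth: float = 1.0) -> "SimParams":
        """Return a copy with perturbation multipliers applied to wild type.

        Adhesion multipliers act on the experimental adhesion measure, so the
        corresponding contact energies are *divided* by the multiplier
        (adhesion and contact energy are inversely related).  ``growth`` > 1
        means faster proliferation (shorter mean time to mitosis).
        """
        for name, m in (("proteolysis", proteolysis),
                        ("scc_scc_adhesion", scc_scc_adhesion),
                        ("scc_ecm_adhesion", scc_ecm_adhesion),
                        ("growth", growth)):
            if m <= 0:
                raise ValueError(f"multiplier {name} must be > 0")
        return dataclasses.replace(
            self,
            degradation_rate_scc=self.degradation_rate_scc * proteolysis,
            degradation_rate_caf=self.degradation_rate_caf * caf_degradation,
            pushing_rate_caf=self.pushing_rate_caf * caf_pushing,
            j_scc_scc=self.j_scc_scc / scc_scc_adhesion,
            j_scc_ecm=self.j_scc_ecm / scc_ecm_adhesion,
            j_scc_ecm_zero=self.j_scc_ecm_zero / scc_ecm_adhesion,
            taxis_energy_scc=self.taxis_energy_scc * taxis,
            mean_time_to_mitosis=self.mean_time_to_mitosis / growth,
        )

    def contact_matrix(self) -> np.ndarray:
        """4x4 contact-energy table indexed by kind (medium, SCC, CAF, air).

        The SCC-medium entry holds the full-density value; the density
        interpolation J(rho) = J_zero + (J_full - J_zero) * rho is applied in
        the kernels per matrix voxel.
        """
        J = np.zeros((4, 4), dtype=np.float64)
        J[KIND_SCC, KIND_SCC] = self.j_scc_scc
        J[KIND_SCC, KIND_CAF] = J[KIND_CAF, KIND_SCC] = self.j_scc_caf
        J[KIND_CAF, KIND_CAF] = self.j_caf_caf
        J[KIND_SCC, KIND_MEDIUM] = J[KIND_MEDIUM, KIND_SCC] = self.j_scc_ecm
        J[KIND_CAF, KIND_MEDIUM] = J[KIND_MEDIUM, KIND_CAF] = self.j_caf_ecm
        J[KIND_AIR, KIND_SCC] = J[KIND_SCC, KIND_AIR] = self.j_air_cell
        J[KIND_AIR, KIND_CAF] = J[KIND_CAF, KIND_AIR] = self.j_air_cell
        return J

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d
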