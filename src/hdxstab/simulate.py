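"""Forward simulation of the differential HDX-MS experiment.

Generates everything the analysis stages consume, with known ground truth:
per-residue EX2 exchange under protection factors, ligand-coupled
stabilization (fast-exchange or slow two-population), peptide-level centroid
observation with back exchange and Gaussian centroid noise, maxD controls,
isotopic envelopes, PLIMSTEX titrations and proteolysis decay curves.

The exchange model is the EX2 closed form per residue i:

    D_i(t) = f_D * (1 - exp(-(k_int,i / P_i) * t))

with f_D the maximal exchangeable fraction set by the labeling dilution
(0.9 for a 10-fold dilution into D2O), k_int the intrinsic rate and P_i the
protection factor.  Ligand binding multiplies P_i by exp(delta_ln_P_i) in
the bound state.  In the fast-exchange limit the two states share one
population with rate (1-theta) k_free + theta k_bound; in the slow limit the
spectrum carries two populations with weights (1-theta, theta) whose
centroid — but not shape — matches the occupancy-weighted mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from pyteomics import mass as pt_mass

from .errors import UsageError, ValidationError
from .exchange import DEUTERON_MASS_SHIFT, PeptideUptakeRecord, reporter_residues
from .io import ProteinEntry, StateTable
from .plimstex import TitrationSeries
from .proteolysis import ProteolysisTimecourse
from .rates import compute_intrinsic_rates

__all__ = [
    "SyntheticSystem",
    "LigandCoupling",
    "ProteolysisModel",
    "ExchangePopulations",
    "simulate_residue_exchange",
    "simulate_peptide_uptake",
    "simulate_isotope_envelope",
    "simulate_titration",
    "simulate_proteolysis_timecourse",
    "ligand_occupancy",
    "calibrate_plimstex_system",
]

#: the six labeling times of the exchange timecourse, seconds (10 s to 16 h)
DEFAULT_LABELING_TIMES = (10.0, 60.0, 600.0, 3600.0, 14400.0, 57600.0)


@dataclass
class SyntheticSystem:
    """Ground-truth description of one protein's exchange behaviour.

    ``log_protection`` holds ln P_i per residue (>= 0 where the residue
    exchanges); ``intrinsic_rates`` k_int per residue in 1/s with zeros at
    prolines and the N-terminal residue.  ``back_exchange_retention`` is the
    per-peptide fraction of label surviving analysis; maxD controls share it.
    """

    protein: ProteinEntry
    log_protection: np.ndarray
    intrinsic_rates: np.ndarray
    label_fraction: float = 0.9
    back_exchange_retention: float = 0.85
    noise_sd: float = 0.20
    deuteron_mass: float = DEUTERON_MASS_SHIFT
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.protein.sequence)
        self.log_protection = np.asarray(self.log_protection, dtype=float)
        self.intrinsic_rates = np.asarray(self.intrinsic_rates, dtype=float)
        if self.log_protection.shape != (n,) or self.intrinsic_rates.shape != (n,):
            raise ValidationError("per-residue arrays must match sequence length")
        exchanging = self.intrinsic_rates > 0
        if np.any(self.log_protection[exchanging] < 0):
            raise ValidationError("negative ln(protection) at an exchanging residue")
        if not 0.0 < self.label_fraction <= 1.0:
            raise ValidationError("label_fraction must be in (0, 1]")
        if not 0.0 < self.back_exchange_retention <= 1.0:
            raise ValidationError("back_exchange_retention must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.intrinsic_rates[0] != 0.0:
            raise ValidationError("protein N-terminal residue must have k_int = 0")
        for i, aa in enumerate(self.protein.sequence):
            if aa == "P" and self.intrinsic_rates[i] != 0.0:
                raise ValidationError(f"proline at position {i + 1} must have k_int = 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class LigandCoupling:
    """Ligand-coupled protection: one stabilizer per light-chain dimer.

    ``delta_log_protection`` is the per-residue increment to ln P in the
    bound state (zero outside the binding footprint).  ``midpoint`` is the
    occupancy midpoint in μM; by default occupancy follows the
    phenomenological hyperbola theta = L / (midpoint + L), with an exact
    1:1 dimer:ligand mass-balance mode available for thermodynamic use.
    """

    midpoint: float
    delta_log_protection: np.ndarray
    mode: str = "fast_exchange"
    stoichiometry: int = 1
    occupancy_model: str = "hyperbolic"
    protein_total: float = 0.25  # μM, binding-competent (dimer) concentration

    def __post_init__(self) -> None:
        if self.midpoint <= 0:
            raise ValidationError("midpoint must be positive")
        self.delta_log_protection = np.asarray(self.delta_log_protection, dtype=float)
        if np.any(self.delta_log_protection < 0):
            raise ValidationError("delta_log_protection increments must be >= 0")
        if self.mode not in ("fast_exchange", "slow_two_population"):
            raise UsageError(f"unknown coupling mode {self.mode!r}")
        if self.stoichiometry != 1:
            raise ValidationError("stoichiometry is fixed at one ligand per dimer")


@dataclass
class ProteolysisModel:
    """First-order intact-protein decay, with and without saturating stabilizer."""

    rate: float  # 1/h, vehicle
    rate_bound: float  # 1/h, with saturating stabilizer
    noise_sd: float = 0.03
    timepoints: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 24.0)

    def __post_init__(self) -> None:
        if self.rate < 0 or self.rate_bound < 0:
            raise ValidationError("decay rates must be non-negative")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")


@dataclass
class ExchangePopulations:
    """Per-population residue deuterium fractions, shape (n_times, n_residues)."""

    weights: tuple[float, ...]
    curves: tuple[np.ndarray, ...]

    def expectation(self) -> np.ndarray:
        """Occupancy-weighted mean curve (what a centroid measures)."""
        out = np.zeros_like(self.curves[0])
        for w, c in zip(self.weights, self.curves):
            out += w * c
        return out


def ligand_occupancy(
    ligand, coupling: LigandCoupling,
):
    """Bound fraction theta at total ligand concentration(s) in μM."""
    L = np.asarray(ligand, dtype=float)
    if coupling.occupancy_model == "hyperbolic":
        theta = L / (coupling.midpoint + L)
    elif coupling.occupancy_model == "quadratic_depletion":
        P = coupling.protein_total
        kd = coupling.midpoint
        s = P + L + kd
        complex_ = (s - np.sqrt(s * s - 4.0 * P * L)) / 2.0
        theta = complex_ / P
    else:
        raise UsageError(f"unknown occupancy model {coupling.occupancy_model!r}")
    return float(theta) if np.isscalar(ligand) else theta


def _ex2_curve(system: SyntheticSystem, rates: np.ndarray, times: np.ndarray) -> np.ndarray:
    curve = system.label_fraction * (1.0 - np.exp(-np.outer(times, rates)))
    curve[:, rates == 0.0] = 0.0
    return curve


def simulate_residue_exchange(
    system: SyntheticSystem,
    times: Sequence[float],
    theta_bound: float = 0.0,
    coupling: LigandCoupling | None = None,
) -> ExchangePopulations:
    """Noiseless per-residue deuterium fractions D_i(t) for each population.

    Without coupling (or at theta 0) a single population is returned.  In
    fast-exchange mode the free and bound rates mix into one effective rate;
    in slow mode both population curves are returned with weights
    (1 - theta, theta).
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValidationError("times must be non-negative")
    if not 0.0 <= theta_bound <= 1.0:
        raise ValidationError("theta_bound must lie in [0, 1]")
    k_free = system.intrinsic_rates / np.exp(system.log_protection)
    if coupling is None or theta_bound == 0.0:
        return ExchangePopulations((1.0,), (_ex2_curve(system, k_free, times),))
    k_bound = k_free / np.exp(coupling.delta_log_protection)
    if coupling.mode == "fast_exchange":
        k_eff = (1.0 - theta_bound) * k_free + theta_bound * k_bound
        return ExchangePopulations((1.0,), (_ex2_curve(system, k_eff, times),))
    return ExchangePopulations(
        (1.0 - theta_bound, theta_bound),
        (_ex2_curve(system, k_free, times), _ex2_curve(system, k_bound, times)),
    )


def _peptide_m0(sequence: str) -> float:
    return float(pt_mass.calculate_mass(sequence=sequence))


def simulate_peptide_uptake(
    system: SyntheticSystem,
    peptides: Sequence[tuple[int, int]],
    times: Sequence[float] = DEFAULT_LABELING_TIMES,
    theta_bound: float = 0.0,
    coupling: LigandCoupling | None = None,
    condition: str = "vehicle",
    replicates: int = 1,
    noise_sd: float | None = None,
    rng: np.random.Generator | None = None,
) -> StateTable:
    """Observe peptide centroids for the given intervals and labeling times.

    Per peptide, the true uptake is the sum of residue deuterium fractions
    over its exchangeable reporters (first two residues, prolines and the
    protein N-terminus excluded) times the deuteron mass; the observed
    centroid is m0 + retention * true_uptake + Gaussian noise.  maxD
    controls are noiseless and share the peptide's retention.
    """
    if rng is None:
        rng = system.rng()
    noise = system.noise_sd if noise_sd is None else noise_sd
    times = np.asarray(times, dtype=float)
    seq = system.protein.sequence
    curves = simulate_residue_exchange(system, times, theta_bound, coupling)
    expectation = curves.expectation()  # (ntimes, nres)
    records: list[PeptideUptakeRecord] = []
    r = system.back_exchange_retention
    dm = system.deuteron_mass
    for start, end in peptides:
        if not (1 <= start <= end <= len(seq)):
            raise ValidationError(f"peptide {start}-{end} outside sequence")
        if end - start + 1 < 3:
            raise ValidationError(
                f"peptide {start}-{end} too short: no exchangeable reporters"
            )
        pep_seq = seq[start - 1 : end]
        reporters = reporter_residues(pep_seq, start)
        idx = [p - 1 for p in reporters]
        m0 = _peptide_m0(pep_seq)
        mmaxd = m0 + r * system.label_fraction * len(idx) * dm
        for ti, t in enumerate(times):
            true_uptake = float(expectation[ti, idx].sum()) * dm
            for rep in range(1, replicates + 1):
                mt = m0 + r * true_uptake
                if noise > 0:
                    mt += rng.normal(0.0, noise)
                records.append(
                    PeptideUptakeRecord(
                        protein=system.protein.name,
                        start=start,
                        end=end,
                        sequence=pep_seq,
                        condition=condition,
                        exposure=float(t),
                        replicate=rep,
                        m0=m0,
                        mt=mt,
                        mmaxD=mmaxd,
                    )
                )
    return StateTable(records=records, proteins=[system.protein])


def simulate_isotope_envelope(
    n_sites: int,
    site_probabilities: Sequence[float],
    base_mz: float,
    charge: int,
    deuteron_mass: float = DEUTERON_MASS_SHIFT,
) -> list[tuple[float, float]]:
    """Deuteration envelope: Poisson-binomial intensities on an m/z grid.

    Peak j carries the probability of exactly j incorporated deuterons,
    located deuteron_mass/charge above its neighbour.
    """
    if charge <= 0:
        raise ValidationError("charge must be a positive integer")
    probs = np.asarray(site_probabilities, dtype=float)
    if probs.shape != (n_sites,):
        raise ValidationError("need one site probability per site")
    if np.any((probs < 0) | (probs > 1)):
        raise ValidationError("site probabilities must lie in [0, 1]")
    # Poisson-binomial by sequential convolution
    dist = np.array([1.0])
    for p in probs:
        dist = np.convolve(dist, [1.0 - p, p])
    return [
        (base_mz + j * deuteron_mass / charge, float(q)) for j, q in enumerate(dist)
    ]


def mix_envelopes(
    envelopes: Sequence[Sequence[tuple[float, float]]], weights: Sequence[float]
) -> list[tuple[float, float]]:
    """Weighted sum of envelopes sharing one m/z grid (slow two-population spectra)."""
    acc: dict[float, float] = {}
    for env, w in zip(envelopes, weights):
        for mz, inten in env:
            acc[mz] = acc.get(mz, 0.0) + w * inten
    return sorted(acc.items())


def simulate_titration(
    system: SyntheticSystem,
    coupling: LigandCoupling,
    peptide: tuple[int, int],
    ligand_concentrations: Sequence[float],
    exposure: float = 5400.0,
    replicates: int = 2,
    noise_sd: float | None = None,
    rng: np.random.Generator | None = None,
) -> TitrationSeries:
    """PLIMSTEX titration: replicate centroid uptakes per ligand concentration."""
    concentrations = list(ligand_concentrations)
    if not concentrations:
        raise UsageError("empty ligand concentration list")
    if rng is None:
        rng = system.rng()
    noise = system.noise_sd if noise_sd is None else noise_sd
    points = []
    for conc in concentrations:
        theta = ligand_occupancy(conc, coupling)
        table = simulate_peptide_uptake(
            system,
            [peptide],
            times=[exposure],
            theta_bound=theta,
            coupling=coupling,
            condition=f"L={conc}",
            replicates=replicates,
            noise_sd=noise,
            rng=rng,
        )
        uptakes = [rec.mt - rec.m0 for rec in table.records]
        points.append((float(conc), uptakes))
    return TitrationSeries(
        protein=system.protein.name,
        peptide=peptide,
        points=points,
        exposure=exposure,
    )


def simulate_proteolysis_timecourse(
    model: ProteolysisModel,
    with_ligand: bool = False,
    seed: int | None = None,
    protein: str = "synthetic",
    rng: np.random.Generator | None = None,
) -> ProteolysisTimecourse:
    """Exponential intact-fraction decay with clipped Gaussian noise."""
    if rng is None:
        rng = np.random.default_rng(seed)
    k = model.rate_bound if with_ligand else model.rate
    t = np.asarray(model.timepoints, dtype=float)
    if np.any(t < 0):
        raise ValidationError("timepoints must be non-negative")
    f = np.exp(-k * t)
    clipped = False
    if model.noise_sd > 0:
        f = f + rng.normal(0.0, model.noise_sd, size=f.shape)
        if np.any((f < 0) | (f > 1)):
            clipped = True
        f = np.clip(f, 0.0, 1.0)
    return ProteolysisTimecourse(
        protein=protein,
        condition="stabilizer" if with_ligand else "vehicle",
        times=t.tolist(),
        fractions=f.tolist(),
        clipped=clipped,
    )


def _protection_for_fraction(
    target_fraction: float, label_fraction: float, k_int: float, exposure: float
) -> float:
    """ln P that yields D = target_fraction at the given exposure (EX2 closed form)."""
    if not 0.0 < target_fraction < label_fraction:
        raise ValidationError(
            f"target per-residue fraction {target_fraction:.4f} not inside "
            f"(0, label_fraction={label_fraction})"
        )
    k_obs = -math.log(1.0 - target_fraction / label_fraction) / exposure
    ln_p = math.log(k_int / k_obs)
    if ln_p < 0:
        raise ValidationError(
            "requested uptake needs negative protection; raise k_int or exposure"
        )
    return ln_p


def calibrate_plimstex_system(
    peptide_sequence: str,
    d0: float,
    delta_d_at_max: float,
    ec50: float,
    l_max: float,
    exposure: float = 5400.0,
    label_fraction: float = 0.9,
    retention: float = 1.0,
    k_int: float = 1.0,
    deuteron_mass: float = DEUTERON_MASS_SHIFT,
    name: str = "synthetic",
    seed: int = 0,
) -> tuple[SyntheticSystem, LigandCoupling, tuple[int, int]]:
    """Build a system whose titration reproduces stated PLIMSTEX observables.

    ``d0`` is the unliganded centroid uptake (Da) at the given exposure and
    ``delta_d_at_max`` the signed change observed at the top concentration
    ``l_max`` — the convention in which titration endpoints are usually
    quoted.  The bound-state asymptote is therefore set to
    d0 + delta_d_at_max / theta(l_max) so the generated series follows
    uptake(L) = d0 + delta * theta(L) exactly, using the slow two-population
    coupling whose centroid is linear in occupancy.

    Returns the system, the coupling, and the peptide interval (the protein
    is the peptide itself, so reporters are residues 3..N minus prolines).
    """
    protein = ProteinEntry(name=name, sequence=peptide_sequence)
    n = len(peptide_sequence)
    interval = (1, n)
    reporters = reporter_residues(peptide_sequence, 1)
    if not reporters:
        raise ValidationError("peptide has no exchangeable reporters")
    n_rep = len(reporters)
    theta_max = l_max / (ec50 + l_max)
    delta_asym = delta_d_at_max / theta_max
    frac_free = d0 / (n_rep * deuteron_mass * retention)
    frac_bound = (d0 + delta_asym) / (n_rep * deuteron_mass * retention)
    lnp_free = _protection_for_fraction(frac_free, label_fraction, k_int, exposure)
    lnp_bound = _protection_for_fraction(frac_bound, label_fraction, k_int, exposure)
    if lnp_bound < lnp_free:
        raise ValidationError(
            "bound state less protected than free: delta_d_at_max must be a reduction"
        )
    rates = compute_intrinsic_rates(peptide_sequence, override=k_int)
    log_protection = np.zeros(n)
    delta_lnp = np.zeros(n)
    for pos in reporters:
        log_protection[pos - 1] = lnp_free
        delta_lnp[pos - 1] = lnp_bound - lnp_free
    system = SyntheticSystem(
        protein=protein,
        log_protection=log_protection,
        intrinsic_rates=rates,
        label_fraction=label_fraction,
        back_exchange_retention=retention,
        noise_sd=0.20,
        deuteron_mass=deuteron_mass,
        seed=seed,
    )
    coupling = LigandCoupling(
        midpoint=ec50,
        delta_log_protection=delta_lnp,
        mode="slow_two_population",
    )
    return system, coupling, interval
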