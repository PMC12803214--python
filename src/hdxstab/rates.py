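"""Intrinsic (unprotected) backbone amide exchange rates in D2O.

Sequence-dependent reference rates follow the standard poly-DL-alanine
parameterization: for the amide of residue i,

    k_int = kA * 10**(-pD)  +  kB * 10**(pD - pKD)  +  kW

with

    kA = kA_ref * 10**(A_lam(i) + A_rho(i-1))
    kB = kB_ref * 10**(B_lam(i) + B_rho(i-1))
    kW = kW_ref * 10**(B_lam(i) + B_rho(i-1))

where the lambda factor is the inductive/steric effect of the residue's own
side chain on its amide and the rho factor the effect of the preceding
residue's side chain.  Each catalytic term carries its own Arrhenius
temperature correction from the 293 K reference.  Acidic side chains are
taken in their ionized (neutral-pD) forms.  Prolines have no backbone amide
and the protein N-terminal residue has no peptide-bond amide; both get rate
zero and never report.

These reference coefficients calibrate the synthetic-data generator; none
of the analysis-side results depend on them, and a uniform rate override is
available so simulations can be made table-independent.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import ValidationError

# reference rates for poly-DL-alanine at 293 K, D2O; log10 units
_LOG_KA_REF = 1.62   # per (M min)
_LOG_KB_REF = 10.05  # per (M min)
_LOG_KW_REF = -1.5   # per min
_PKD = 15.05         # ion product of D2O at 293 K
_T_REF = 293.0       # K
# Arrhenius activation energies, kcal/mol
_EA_ACID = 14.0
_EA_BASE = 17.0
_EA_WATER = 19.0
_R_KCAL = 1.987e-3  # kcal/(mol K)

# side-chain factors, log10 units relative to alanine:
# residue -> (acid_lambda, acid_rho, base_lambda, base_rho)
SIDE_CHAIN_FACTORS: dict[str, tuple[float, float, float, float]] = {
    "A": (0.00, 0.00, 0.00, 0.00),
    "R": (-0.59, -0.32, 0.08, 0.22),
    "N": (-0.58, -0.13, 0.49, 0.32),
    "D": (0.90, 0.58, 0.10, -0.18),   # ionized carboxylate
    "C": (-0.54, -0.46, 0.62, 0.55),  # reduced
    "Q": (-0.47, -0.27, 0.06, 0.20),
    "E": (-0.90, 0.31, -0.11, -0.15),  # ionized carboxylate
    "G": (-0.22, 0.22, 0.27, 0.17),
    "H": (-0.80, -0.51, 0.80, 0.83),
    "I": (-0.91, -0.59, -0.73, -0.23),
    "L": (-0.57, -0.13, -0.58, -0.21),
    "K": (-0.56, -0.29, -0.04, 0.12),
    "M": (-0.64, -0.28, -0.01, 0.11),
    "F": (-0.52, -0.43, -0.24, 0.06),
    "P": (0.00, -0.19, 0.00, -0.24),  # trans; lambda unused (no amide)
    "S": (-0.44, -0.39, 0.37, 0.30),
    "T": (-0.79, -0.47, -0.07, 0.20),
    "W": (-0.40, -0.44, -0.41, -0.11),
    "Y": (-0.41, -0.37, -0.27, 0.05),
    "V": (-0.74, -0.30, -0.70, -0.14),
}

RATE_TABLE_VERSION = "polyDLA-293K-1"


def _arrhenius(ea_kcal: float, temperature: float) -> float:
    return math.exp(-(ea_kcal / _R_KCAL) * (1.0 / temperature - 1.0 / _T_REF))


def intrinsic_rate(
    residue: str, previous: str, pD: float, temperature: float
) -> float:
    """k_int (1/s) for one amide given its own and the preceding residue."""
    if residue == "P":
        return 0.0
    try:
        a_lam, _, b_lam, _ = SIDE_CHAIN_FACTORS[residue]
        _, a_rho, _, b_rho = SIDE_CHAIN_FACTORS[previous]
    except KeyError as exc:
        raise ValidationError(f"unknown residue code: {exc.args[0]!r}") from exc
    k_acid = 10.0 ** (_LOG_KA_REF + a_lam + a_rho - pD) * _arrhenius(
        _EA_ACID, temperature
    )
    k_base = 10.0 ** (_LOG_KB_REF + b_lam + b_rho + pD - _PKD) * _arrhenius(
        _EA_BASE, temperature
    )
    k_water = 10.0 ** (_LOG_KW_REF + b_lam + b_rho) * _arrhenius(
        _EA_WATER, temperature
    )
    return (k_acid + k_base + k_water) / 60.0  # per min -> per s


def compute_intrinsic_rates(
    sequence: str,
    pD: float = 7.4,
    temperature: float = 293.15,
    override: float | None = None,
) -> np.ndarray:
    """Per-residue intrinsic exchange rates (1/s) for a protein sequence.

    Position 1 (the protein N-terminus) and prolines get rate 0.  With
    ``override``, every exchanging residue gets that uniform rate instead
    of the table value — the mode all deterministic tests use.
    """
    if not sequence:
        raise ValidationError("empty sequence")
    if not 2.0 <= pD <= 10.0:
        raise ValidationError(f"pD {pD} outside supported range [2, 10]")
    if not 273.0 <= temperature <= 333.0:
        raise ValidationError(
            f"temperature {temperature} K outside supported range [273, 333]"
        )
    bad = set(sequence) - set(SIDE_CHAIN_FACTORS)
    if bad:
        raise ValidationError(f"unknown residue code(s): {sorted(bad)}")
    rates = np.zeros(len(sequence), dtype=float)
    for i, aa in enumerate(sequence):
        if i == 0 or aa == "P":
            continue
        if override is not None:
            rates[i] = override
        else:
            rates[i] = intrinsic_rate(aa, sequence[i - 1], pD, temperature)
    return rates
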