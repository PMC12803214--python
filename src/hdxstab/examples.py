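"""Synthetic example systems used in documentation, tests and scripts.

The alignment entry here is a synthetic stand-in for a real light-chain
master alignment: it reproduces the published coordinate conventions (a
219-column master alignment, variable domain in columns 1-113, the
stabilizer-responsive peptide NWVFGGGTKL occupying alignment columns
101-110 and sequential residues 98-107 of the AL light chain) with
deterministic filler sequence elsewhere.  It is NOT the real AL sequence.

``PLIMSTEX_REFERENCE_OBSERVABLES`` carries the reference titration
observables for the three AL constructs — the zero-ligand uptake D0, the
signed uptake change at the top of the 0.095-25 μM titration, and the
protection midpoint EC50 — used as generator inputs for round-trip
demonstrations.
"""

from __future__ import annotations

from itertools import cycle, islice

from .io import ProteinEntry

#: peptide spanning CDR3/FR4 at the dimer interface; alignment columns 101-110
INTERFACE_PEPTIDE = "NWVFGGGTKL"

MASTER_ALIGNMENT_LENGTH = 219
DOMAIN_BOUNDARY = 113  # last variable-domain column

#: reference titration observables per AL construct:
#: (D0 in Da, signed delta-D at 25 uM in Da, EC50 in uM)
PLIMSTEX_REFERENCE_OBSERVABLES: dict[str, dict[str, float]] = {
    "AL LC": {"d0": 3.73, "delta_d": -1.37, "ec50": 0.65},
    "AL C218S": {"d0": 5.20, "delta_d": -2.85, "ec50": 1.8},
    "AL VL": {"d0": 6.34, "delta_d": -2.61, "ec50": 2.2},
}

#: 2-fold serial titration grid, μM: 0.095 (= 25/2^8) up to 25, plus vehicle
TITRATION_GRID_UM = tuple([0.0] + [25.0 / 2**k for k in reversed(range(9))])

PLIMSTEX_EXPOSURE_S = 5400.0  # 90 min labeling

_FILLER = "QSVLTQASVSGSLGQRVTISCTGSSSDVGGYNYVS"  # proline-free filler motif


def _filler(n: int) -> str:
    return "".join(islice(cycle(_FILLER), n))


def synthetic_light_chain_entry(name: str = "AL") -> ProteinEntry:
    """Synthetic AL-like entry on the 219-column master alignment.

    Three gap columns (28-30) sit before the interface peptide, so alignment
    columns 101-110 (NWVFGGGTKL) correspond to sequential residues 98-107;
    the constant domain fills columns 114-219.
    """
    row = (
        _filler(27)  # columns 1-27
        + "---"  # columns 28-30 (CDR1-adjacent gaps)
        + _filler(70)  # columns 31-100
        + INTERFACE_PEPTIDE  # columns 101-110
        + _filler(109)  # columns 111-219
    )
    assert len(row) == MASTER_ALIGNMENT_LENGTH
    return ProteinEntry(
        name=name,
        sequence=row.replace("-", ""),
        alignment_row=row,
        domain_boundary=DOMAIN_BOUNDARY,
        region_annotations=[
            ("CDR3", 89, 100),
            ("FR4", 101, 113),
        ],
    )


def synthetic_gapless_entry(name: str = "GL") -> ProteinEntry:
    """A gapless companion entry (identity coordinate map)."""
    row = _filler(MASTER_ALIGNMENT_LENGTH)
    return ProteinEntry(name=name, sequence=row, alignment_row=row)


def reference_titration_fit(
    construct: str,
    noise_sd: float = 0.0,
    replicates: int = 1,
    rng=None,
    seed: int = 0,
):
    """Round-trip fit of a reference titration for one AL construct.

    Generates the titration on the 2-fold 0.095-25 μM grid (plus vehicle) at
    90 min exposure from the reference observables, then fits the unimolar
    protection model.  Noiseless by default; pass ``noise_sd``/``replicates``
    (and an ``rng``) for Monte-Carlo use.
    """
    from .plimstex import fit_titration
    from .simulate import calibrate_plimstex_system, simulate_titration

    obs = PLIMSTEX_REFERENCE_OBSERVABLES[construct]
    system, coupling, interval = calibrate_plimstex_system(
        INTERFACE_PEPTIDE,
        obs["d0"],
        obs["delta_d"],
        obs["ec50"],
        l_max=max(TITRATION_GRID_UM),
        exposure=PLIMSTEX_EXPOSURE_S,
        seed=seed,
    )
    series = simulate_titration(
        system,
        coupling,
        interval,
        TITRATION_GRID_UM,
        exposure=PLIMSTEX_EXPOSURE_S,
        replicates=replicates,
        noise_sd=noise_sd,
        rng=rng,
    )
    return fit_titration(series)
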