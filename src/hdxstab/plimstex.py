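"""PLIMSTEX titration analysis.

In a PLIMSTEX experiment (Protein-Ligand Interaction by Mass Spectrometry,
Titration and H/D EXchange) the labeling time is fixed and ligand binding is
read out as a concentration-dependent change in peptide deuterium uptake.
The default model is the unimolar (one ligand per light-chain dimer)
protection hyperbola

    uptake(L) = D0 + dDmax * L / (EC50 + L)

where D0 is the uptake without ligand, dDmax the signed asymptotic change,
and EC50 the protection midpoint — the concentration of 50% maximal effect.
The midpoint is deliberately reported as an EC50 and not a dissociation
constant: dimerization equilibria and exchange endpoints differ between
constructs, so the fitted midpoint is a phenomenological potency measure.
A depletion-aware variant replaces L by the free-ligand concentration from
the exact 1:1 dimer:ligand mass balance for users who want a thermodynamic
reading at total concentrations comparable to the protein's.

The Model/Results pair follows the statsmodels idiom: build a
:class:`TitrationModel` from data, call :meth:`~TitrationModel.fit`, and
work with the returned :class:`BindingFit`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import lmfit
import numpy as np

from .errors import FitError, UsageError, ValidationError
from .exchange import centroid_mass

__all__ = [
    "TitrationSeries",
    "TitrationModel",
    "BindingFit",
    "evaluate_binding_model",
    "fit_titration",
    "mixture_centroid",
    "free_ligand_depletion",
]


@dataclass
class TitrationSeries:
    """A ligand-concentration series of centroid uptake measurements.

    ``points`` maps each ligand concentration (μM) to the replicate centroid
    uptakes (Da).  ``peptide`` is the (start, end) interval in alignment
    coordinates; ``exposure`` the fixed labeling time in seconds.
    """

    protein: str
    peptide: tuple[int, int]
    points: list[tuple[float, list[float]]]
    exposure: float = 5400.0
    spectra: list[list[tuple[float, float]]] | None = None

    def __post_init__(self) -> None:
        concs = [c for c, _ in self.points]
        if any(c < 0 for c in concs):
            raise ValidationError("ligand concentrations must be non-negative")
        if len(set(concs)) != len(concs):
            raise ValidationError("ligand concentrations must be distinct")

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _ in self.points], dtype=float)

    @property
    def mean_uptakes(self) -> np.ndarray:
        return np.array([float(np.mean(u)) for _, u in self.points], dtype=float)


def free_ligand_depletion(total_ligand, kd: float, total_protein: float):
    """Free-ligand concentration from the exact 1:1 mass balance.

    Solves ``PL = P_free * L_free / Kd`` with conservation of both species;
    ``total_protein`` is the binding-competent (dimer) concentration, same
    units as ligand.
    """
    L = np.asarray(total_ligand, dtype=float)
    P = total_protein
    s = P + L + kd
    complex_ = (s - np.sqrt(s * s - 4.0 * P * L)) / 2.0
    return L - complex_


def evaluate_binding_model(
    d0: float,
    delta_d_max: float,
    ec50: float,
    ligand,
    model: str = "hyperbolic",
    protein_total: float = 0.25,
):
    """Predicted centroid uptake (Da) at ligand concentration(s) ``ligand`` (μM)."""
    if ec50 <= 0:
        raise ValidationError("ec50 must be positive")
    L = np.asarray(ligand, dtype=float)
    if np.any(L < 0):
        raise ValidationError("ligand concentrations must be non-negative")
    if model == "hyperbolic":
        eff = L
    elif model == "quadratic_depletion":
        eff = free_ligand_depletion(L, ec50, protein_total)
    else:
        raise UsageError(f"unknown binding model {model!r}")
    out = d0 + delta_d_max * eff / (ec50 + eff)
    return float(out) if np.isscalar(ligand) else out


@dataclass
class BindingFit:
    """Results of a PLIMSTEX fit.

    ``delta_uptake`` is the signed change between the highest tested
    concentration and the zero-ligand baseline — the quantity usually
    quoted as ΔD — and differs from the asymptotic ``delta_d_max`` unless
    the top of the titration saturates the site.
    """

    d0: float
    delta_d_max: float
    ec50: float
    d0_stderr: float | None
    delta_d_max_stderr: float | None
    ec50_stderr: float | None
    residual_norm: float
    model: str
    delta_uptake: float
    unidentifiable: bool = False
    n_points: int = 0
    protein_total: float = 0.25

    @property
    def delta_uptake_magnitude(self) -> float:
        return abs(self.delta_uptake)

    def predict(self, ligand):
        return evaluate_binding_model(
            self.d0, self.delta_d_max, self.ec50, ligand,
            model=self.model, protein_total=self.protein_total,
        )

    def summary(self) -> str:
        def fmt(v, e):
            if e is None or not math.isfinite(e):
                return f"{v:10.4g}         --"
            return f"{v:10.4g} {e:10.3g}"

        lines = [
            "PLIMSTEX binding fit",
            "=" * 46,
            f"model:            {self.model}",
            f"n concentrations: {self.n_points}",
            "",
            "parameter            value     stderr",
            "-" * 46,
            f"D0 (Da)         {fmt(self.d0, self.d0_stderr)}",
            f"dDmax (Da)      {fmt(self.delta_d_max, self.delta_d_max_stderr)}",
            f"EC50 (uM)       {fmt(self.ec50, self.ec50_stderr)}",
            "-" * 46,
            f"dD at top concentration (Da): {self.delta_uptake:.4g} "
            f"(|dD| = {self.delta_uptake_magnitude:.4g})",
            f"residual norm (Da):           {self.residual_norm:.3g}",
        ]
        if self.unidentifiable:
            lines.append("WARNING: flat titration - midpoint unidentifiable")
        return "\n".join(lines)


class TitrationModel:
    """Nonlinear least-squares model for a PLIMSTEX titration.

    Parameters
    ----------
    concentrations, uptakes
        Ligand concentrations (μM) and the replicate-mean centroid uptakes
        (Da) at each.  At least four distinct concentrations are required.
    model
        "hyperbolic" (default) or "quadratic_depletion".
    protein_total
        Binding-competent protein concentration (μM) for the depletion model.
    """

    def __init__(
        self,
        concentrations: Sequence[float],
        uptakes: Sequence[float],
        model: str = "hyperbolic",
        protein_total: float = 0.25,
    ) -> None:
        self.concentrations = np.asarray(concentrations, dtype=float)
        self.uptakes = np.asarray(uptakes, dtype=float)
        if self.concentrations.shape != self.uptakes.shape:
            raise UsageError("concentrations and uptakes must have equal length")
        if len(np.unique(self.concentrations)) < 4:
            raise UsageError("need at least 4 distinct concentrations to fit")
        if model not in ("hyperbolic", "quadratic_depletion"):
            raise UsageError(f"unknown binding model {model!r}")
        self.model = model
        self.protein_total = protein_total

    @classmethod
    def from_series(
        cls, series: TitrationSeries, model: str = "hyperbolic",
        protein_total: float = 0.25,
    ) -> "TitrationModel":
        return cls(
            series.concentrations, series.mean_uptakes,
            model=model, protein_total=protein_total,
        )

    def _initial_values(self) -> tuple[float, float, float]:
        order = np.argsort(self.concentrations)
        L = self.concentrations[order]
        u = self.uptakes[order]
        d0 = float(u[0])
        dmax = float(u[-1] - u[0])
        if dmax == 0.0:
            half = L[len(L) // 2]
        else:
            target = d0 + dmax / 2.0
            half = float(L[np.argmin(np.abs(u - target))])
        positive = L[L > 0]
        if half <= 0:
            half = float(positive[0]) if positive.size else 1.0
        return d0, dmax, half

    def fit(self) -> BindingFit:
        d0_init, dmax_init, ec50_init = self._initial_values()
        params = lmfit.Parameters()
        params.add("d0", value=d0_init)
        params.add("delta_d_max", value=dmax_init if dmax_init != 0 else -1e-6)
        params.add("ec50", value=ec50_init, min=1e-9)

        def residual(p):
            pred = evaluate_binding_model(
                p["d0"].value, p["delta_d_max"].value, p["ec50"].value,
                self.concentrations, model=self.model,
                protein_total=self.protein_total,
            )
            return pred - self.uptakes

        result = lmfit.minimize(residual, params, method="leastsq")
        if not result.success:
            raise FitError("titration fit did not converge", result.message)
        p = result.params
        resid = residual(p)
        span = float(self.uptakes.max() - self.uptakes.min())
        noise_scale = max(float(np.std(resid)), 1e-12)
        unidentifiable = abs(p["delta_d_max"].value) < 3.0 * noise_scale or span == 0.0
        top = float(self.concentrations.max())
        delta_uptake = float(
            evaluate_binding_model(
                p["d0"].value, p["delta_d_max"].value, p["ec50"].value, top,
                model=self.model, protein_total=self.protein_total,
            )
            - p["d0"].value
        )
        return BindingFit(
            d0=p["d0"].value,
            delta_d_max=p["delta_d_max"].value,
            ec50=p["ec50"].value,
            d0_stderr=p["d0"].stderr,
            delta_d_max_stderr=p["delta_d_max"].stderr,
            ec50_stderr=p["ec50"].stderr,
            residual_norm=float(np.linalg.norm(resid)),
            model=self.model,
            delta_uptake=delta_uptake,
            unidentifiable=bool(unidentifiable),
            n_points=len(self.concentrations),
            protein_total=self.protein_total,
        )


def fit_titration(
    series: TitrationSeries, model: str = "hyperbolic",
    protein_total: float = 0.25,
) -> BindingFit:
    """Fit a titration series; replicates are averaged per concentration."""
    return TitrationModel.from_series(
        series, model=model, protein_total=protein_total
    ).fit()


def mixture_centroid(
    spectra: Sequence[Sequence[tuple[float, float]]], charge: int = 1
) -> list[tuple[float, float]]:
    """Per-spectrum neutral centroid mass and bimodality score.

    The bimodality score compares the intensity-weighted variance of the
    m/z profile against the best two-segment split: score = 1 - SSE2/SSE1,
    where SSE1 is the weighted squared deviation about the global centroid
    and SSE2 the minimum over contiguous splits of the summed within-segment
    deviations.  Narrow unimodal envelopes score low; well-separated
    two-population envelopes approach 1.  The score is reported, never
    thresholded.
    """
    out = []
    for peaks in spectra:
        if not peaks:
            raise ValidationError("empty spectrum")
        centroid = centroid_mass(peaks, charge)
        mz = np.array([p[0] for p in peaks], dtype=float)
        w = np.array([p[1] for p in peaks], dtype=float)
        order = np.argsort(mz)
        mz, w = mz[order], w[order]
        total = w.sum()
        mu = (mz * w).sum() / total
        sse1 = float((w * (mz - mu) ** 2).sum())
        if sse1 <= 0:
            out.append((centroid, 0.0))
            continue
        best = sse1
        for s in range(1, len(mz)):
            wl, wr = w[:s], w[s:]
            if wl.sum() <= 0 or wr.sum() <= 0:
                continue
            mul = (mz[:s] * wl).sum() / wl.sum()
            mur = (mz[s:] * wr).sum() / wr.sum()
            sse2 = float((wl * (mz[:s] - mul) ** 2).sum() + (wr * (mz[s:] - mur) ** 2).sum())
            best = min(best, sse2)
        out.append((centroid, 1.0 - best / sse1))
    return out
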