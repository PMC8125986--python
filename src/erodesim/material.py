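"""Elastic-modulus-vs-mass-loss material models and mass/volume conversion.

During enzymatic degradation the tensile elastic modulus of a polymer
filament drops as material is removed.  Over the mass-loss range covered by
the experiments the relationship is well captured by a quadratic

    E(m) = a * m**2 + b * m + c

with E in MPa and m the mass loss in percent.  Built-in coefficient sets are
provided for pure polycaprolactone (PCL) and for the PCL:MCC 98:2 composite
(2 % wt:wt microcrystalline cellulose); both were obtained from tensile
tests on 1.9 mm extruded filaments degraded in a lipase suspension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModulusModel",
    "fit_modulus_model",
    "predict_modulus",
    "mass_to_volume_loss",
    "PRESETS",
    "get_preset",
]


@dataclass(frozen=True)
class ModulusModel:
    """Quadratic elastic-modulus model E = a*m^2 + b*m + c.

    ``a`` (MPa/%^2) and ``b`` (MPa/%) are typically negative (the modulus
    falls with mass loss); ``c`` (MPa) is the undegraded modulus and must
    be positive.
    """

    a: float
    b: float
    c: float
    label: str = ""

    def __post_init__(self):
        if not self.c > 0:
            raise ValueError("intercept c (modulus at zero mass loss) must be > 0")

    def predict(self, mass_loss_pct):
        """Elastic modulus (MPa) at the given mass loss (%).

        Accepts a scalar or array; mass loss must be non-negative.
        """
        m = np.asarray(mass_loss_pct, dtype=float)
        if np.any(m < 0):
            raise ValueError("mass loss must be non-negative")
        e = self.a * m**2 + self.b * m + self.c
        return float(e) if np.isscalar(mass_loss_pct) else e

    @classmethod
    def fit(cls, points, label: str = "fitted") -> "ModulusModel":
        """Least-squares quadratic fit to (mass-loss %, modulus MPa) points.

        Needs at least three distinct abscissae.
        """
        pts = np.asarray(list(points), dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be (mass_loss_pct, modulus_MPa) pairs")
        m, e = pts[:, 0], pts[:, 1]
        if np.unique(m).size < 3:
            raise ValueError(
                "quadratic fit needs >= 3 distinct mass-loss values "
                f"(got {np.unique(m).size})"
            )
        # highest-degree-first polynomial least squares
        a, b, c = np.polyfit(m, e, deg=2)
        return cls(a=float(a), b=float(b), c=float(c), label=label)


def predict_modulus(model: ModulusModel, mass_loss_pct):
    """Functional alias for :meth:`ModulusModel.predict`."""
    return model.predict(mass_loss_pct)


def fit_modulus_model(points, label: str = "fitted") -> ModulusModel:
    """Functional alias for :meth:`ModulusModel.fit`."""
    return ModulusModel.fit(points, label=label)


#: built-in coefficient sets from the filament degradation experiments
PRESETS = {
    "pcl": ModulusModel(a=-0.8489, b=-1.3253, c=306.38, label="PCL"),
    "pcl_mcc_98_2": ModulusModel(
        a=-0.2552, b=-0.5031, c=292.45, label="PCL:MCC 98:2"
    ),
}


def get_preset(name: str) -> ModulusModel:
    """Look up a built-in modulus model by name ('pcl' or 'pcl_mcc_98_2')."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown material preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def mass_to_volume_loss(mass_loss_pct, densities=None, initial_density=None):
    """Convert mass-loss percentages to volume-loss percentages.

    With no density information the two are identical (constant-density
    assumption).  When per-measurement densities (g/cm^3) are supplied, the
    remaining volume is remaining mass / density, so

        vol_loss % = 100 * (1 - (1 - mass_loss/100) * rho_0 / rho_t)

    with ``rho_0`` the undegraded density (defaults to the first entry of
    ``densities``).  A uniform density cancels out and reproduces the
    identity.
    """
    m = np.asarray(mass_loss_pct, dtype=float)
    if np.any(m < 0) or np.any(m >= 100):
        raise ValueError("mass loss must lie in [0, 100)")
    if densities is None:
        return float(m) if np.isscalar(mass_loss_pct) else m
    rho = np.asarray(densities, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("densities must be positive")
    rho0 = float(rho.flat[0]) if initial_density is None else float(initial_density)
    if rho0 <= 0:
        raise ValueError("initial density must be positive")
    out = 100.0 * (1.0 - (1.0 - m / 100.0) * rho0 / rho)
    return float(out.flat[0]) if np.isscalar(mass_loss_pct) else out
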