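"""Neo-Hookean material calibration for the intestinal wall layers.

The compressible neo-Hookean strain energy used throughout the package is

    W = C (I1_bar - 3) + (1/D) [ (J^2 - 1)/2 - ln J ]

with C = G/2 (half the shear modulus) and D = 2/K (twice the inverse bulk
modulus). Given a measured Young's modulus E and a Poisson ratio nu the
small-strain elasticity relations give

    C = E / (4 (1 + nu)),        D = 6 (1 - 2 nu) / E.

Soft intestinal tissue is treated as nearly incompressible (nu = 0.49 by
default); nu = 0.5 yields D = 0, the exactly incompressible limit, in
which the volumetric term is dropped and J = 1 is enforced.

Layer moduli are obtained from three uniaxial measurements on porcine
tissue (intact wall, submucosa + muscularis with mucosa scraped off, and
isolated submucosa) through a thickness-weighted parallel (iso-strain)
rule of mixtures, then transferred to another subject group (e.g. human,
where only intact tissue can be tested) by scaling all layers with the
ratio of intact moduli.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .errors import InconsistentMeasurementsError, InvalidParameterError, NonPhysicalParameterError
from .geometry import DEFAULT_LAYER_FRACTIONS

#: Poisson ratio used for all layers unless overridden.
DEFAULT_POISSON = 0.49

#: Mean Young's moduli (MPa) measured on porcine jejunum.
PIG_E_INTACT = 1.56
PIG_E_SUBMUCOSA_MUSCULARIS = 1.01   # mucosa removed
PIG_E_SUBMUCOSA = 1.35              # isolated submucosa

#: Mean Young's modulus (MPa) of intact pediatric human small intestine.
HUMAN_E_INTACT = 2.63

VALID_LAYER_NAMES = ("mucosa", "submucosa", "muscularis", "mesentery")


def neo_hookean_constants(E: float, nu: float) -> tuple[float, float]:
    """Material constants (C [MPa], D [1/MPa]) from (E [MPa], nu).

    C = E/(4(1+nu)); D = 6(1-2nu)/E. nu = 0.5 gives D = 0 exactly.
    """
    if E <= 0:
        raise InvalidParameterError(f"Young's modulus must be > 0, got {E}")
    if not (0.0 <= nu <= 0.5):
        raise NonPhysicalParameterError(
            f"Poisson ratio must lie in [0, 0.5], got {nu}")
    C = E / (4.0 * (1.0 + nu))
    D = 6.0 * (1.0 - 2.0 * nu) / E
    return C, D


@dataclass(frozen=True)
class LayerMaterial:
    """One layer's calibrated constants.

    C relates to the shear modulus (G = 2C); D is the volumetric
    compliance (K = 2/D). Both follow from (E, nu) — use
    :meth:`from_young` rather than filling C, D by hand.
    """

    name: str
    young_modulus: float  # MPa
    poisson: float
    C: float  # MPa
    D: float  # 1/MPa

    @classmethod
    def from_young(cls, name: str, E: float, nu: float = DEFAULT_POISSON) -> "LayerMaterial":
        C, D = neo_hookean_constants(E, nu)
        return cls(name=name, young_modulus=E, poisson=nu, C=C, D=D)

    @property
    def shear_modulus(self) -> float:
        return 2.0 * self.C

    @property
    def bulk_modulus(self) -> float:
        if self.D == 0.0:
            return float("inf")
        return 2.0 / self.D


def decompose_pig_layers(
    E_intact: float = PIG_E_INTACT,
    E_sm_mp: float = PIG_E_SUBMUCOSA_MUSCULARIS,
    E_sm: float = PIG_E_SUBMUCOSA,
    fractions: Sequence[float] = DEFAULT_LAYER_FRACTIONS,
) -> dict[str, float]:
    """Per-layer Young's moduli from the three porcine measurements.

    Inputs: intact wall modulus, submucosa+muscularis composite modulus
    (mucosa scraped off), isolated submucosa modulus. A parallel
    iso-strain rule of mixtures weighted by the layer thickness
    fractions (f_mu, f_sm, f_mp) gives

        E_sm_mp = (f_sm E_sm + f_mp E_mp) / (f_sm + f_mp)
        E_intact = f_mu E_mu + f_sm E_sm + f_mp E_mp

    solved for E_mp then E_mu. Returns {'mucosa','submucosa','muscularis'}.
    """
    if min(E_intact, E_sm_mp, E_sm) <= 0:
        raise InvalidParameterError("all measured moduli must be > 0")
    f_mu, f_sm, f_mp = fractions
    E_mp = (E_sm_mp * (f_sm + f_mp) - E_sm * f_sm) / f_mp
    E_mu = (E_intact - f_sm * E_sm - f_mp * E_mp) / f_mu
    layers = {"mucosa": E_mu, "submucosa": E_sm, "muscularis": E_mp}
    bad = {k: v for k, v in layers.items() if v <= 0}
    if bad:
        raise InconsistentMeasurementsError(
            f"layer decomposition produced non-positive moduli: {bad}")
    return layers


def composite_modulus(
    layers: Mapping[str, float],
    fractions: Sequence[float] = DEFAULT_LAYER_FRACTIONS,
) -> float:
    """Iso-strain composite modulus of the three wall layers."""
    f_mu, f_sm, f_mp = fractions
    return f_mu * layers["mucosa"] + f_sm * layers["submucosa"] + f_mp * layers["muscularis"]


def scale_layers_to_subject(
    E_intact_subject: float,
    pig_layers: Mapping[str, float],
    E_intact_pig: float | None = None,
    fractions: Sequence[float] = DEFAULT_LAYER_FRACTIONS,
) -> dict[str, float]:
    """Transfer the porcine layer-modulus ratios to another subject.

    Every layer is multiplied by E_intact_subject / E_intact_pig, where
    the pig intact modulus defaults to the iso-strain composite of
    ``pig_layers`` (so the scaled composite equals E_intact_subject
    exactly).
    """
    if E_intact_subject <= 0:
        raise InvalidParameterError("subject intact modulus must be > 0")
    if E_intact_pig is None:
        E_intact_pig = composite_modulus(pig_layers, fractions)
    factor = E_intact_subject / E_intact_pig
    return {name: E * factor for name, E in pig_layers.items()}


def build_material_set(
    layer_moduli: Mapping[str, float],
    nu: float = DEFAULT_POISSON,
    mesentery_like: str = "submucosa",
) -> dict[str, LayerMaterial]:
    """Materialize LayerMaterial objects for the wall layers + mesentery.

    The mesentery has no dedicated measurement; it defaults to the
    constants of ``mesentery_like`` (submucosa unless configured).
    """
    mats = {
        name: LayerMaterial.from_young(name, E, nu)
        for name, E in layer_moduli.items()
    }
    if "mesentery" not in mats:
        donor = mats[mesentery_like]
        mats["mesentery"] = LayerMaterial.from_young(
            "mesentery", donor.young_modulus, donor.poisson)
    return mats


def default_human_material_set(nu: float = DEFAULT_POISSON) -> dict[str, LayerMaterial]:
    """Human wall layers: porcine decomposition scaled to the human intact mean."""
    pig = decompose_pig_layers()
    human = scale_layers_to_subject(HUMAN_E_INTACT, pig)
    return build_material_set(human, nu=nu)


def default_pig_material_set(nu: float = DEFAULT_POISSON) -> dict[str, LayerMaterial]:
    """Porcine wall layers straight from the layer decomposition."""
    return build_material_set(decompose_pig_layers(), nu=nu)


def write_material_set(mats: Mapping[str, LayerMaterial], path: str | Path) -> None:
    payload = [
        {"name": m.name, "E_MPa": m.young_modulus, "nu": m.poisson,
         "C_MPa": m.C, "D_perMPa": m.D}
        for m in mats.values()
    ]
    path = Path(path)
    if path.suffix in (".yml", ".yaml"):
        import yaml
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2))


def read_material_set(path: str | Path) -> dict[str, LayerMaterial]:
    path = Path(path)
    if path.suffix in (".yml", ".yaml"):
        import yaml
        payload = yaml.safe_load(path.read_text())
    else:
        payload = json.loads(path.read_text())
    return {
        entry["name"]: LayerMaterial.from_young(
            entry["name"], float(entry["E_MPa"]), float(entry["nu"]))
        for entry in payload
    }
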