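"""Material data and constitutive models for the restoration-bone system.

Covers the elastic constants of every component, the Misch D1-D4 bone
quality classes (cortical thickness + cancellous stiffness), the linearly
graded cortical-to-cancellous transition zone, and the first-order Ogden
hyperelastic model used for the periodontal ligament.
"""

from __future__ import annotations

from dataclasses import dataclass

E_CORTICAL_GPA = 13.7
TRANSITION_THICKNESS_MM = 0.29


@dataclass(frozen=True)
class MaterialProps:
    name: str
    material: str
    youngs_modulus: float  # GPa
    poisson_ratio: float

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("Young's modulus must be positive")
        if not 0 < self.poisson_ratio < 0.5:
            raise ValueError("Poisson ratio must be in (0, 0.5)")


_REGISTRY: dict[str, MaterialProps] = {
    m.name: m
    for m in [
        MaterialProps("implant", "titanium grade 4", 104.5, 0.37),
        MaterialProps("abutment", "titanium grade 4", 104.5, 0.37),
        MaterialProps("implant_screw", "titanium grade 5", 114.0, 0.33),
        MaterialProps("cement", "glass ionomer cement", 15.9, 0.33),
        MaterialProps("abutment_tooth", "polyurethane", 3.525, 0.33),
        MaterialProps("zirconia_fpd", "zirconium dioxide", 210.0, 0.27),
        MaterialProps("cortical_bone", "cortical bone", 13.7, 0.3),
        MaterialProps("cancellous_bone_d1", "cancellous bone (D1)", 9.5, 0.3),
        MaterialProps("cancellous_bone_d2", "cancellous bone (D2)", 5.5, 0.3),
        MaterialProps("cancellous_bone_d3", "cancellous bone (D3)", 1.6, 0.3),
        MaterialProps("cancellous_bone_d4", "cancellous bone (D4)", 0.69, 0.3),
    ]
}

# convenient aliases
_ALIASES = {
    "titanium_grade4": "implant",
    "titanium_grade5": "implant_screw",
    "cement_layer": "cement",
    "fpd": "zirconia_fpd",
}


def lookup_material(name: str) -> MaterialProps:
    key = _ALIASES.get(name, name)
    try:
        return _REGISTRY[key]
    except KeyError:
        known = sorted(set(_REGISTRY) | set(_ALIASES))
        raise KeyError(
            f"unknown material {name!r}; known materials: {', '.join(known)}"
        ) from None


def material_names() -> list[str]:
    return sorted(_REGISTRY)


@dataclass(frozen=True)
class BoneQualitySpec:
    """Misch bone-quality class: cortical shell thickness and cancellous
    stiffness; cortical modulus is constant across classes."""

    label: str
    cortical_thickness: float  # mm
    e_cancellous: float  # GPa
    e_cortical: float = E_CORTICAL_GPA  # GPa
    transition_thickness: float = TRANSITION_THICKNESS_MM  # mm


_QUALITIES = {
    "D1": BoneQualitySpec("D1", 2.5, 9.5),
    "D2": BoneQualitySpec("D2", 2.0, 5.5),
    "D3": BoneQualitySpec("D3", 1.5, 1.6),
    "D4": BoneQualitySpec("D4", 1.0, 0.69),
}


def bone_quality(label: str) -> BoneQualitySpec:
    try:
        return _QUALITIES[label.upper()]
    except KeyError:
        raise KeyError(
            f"unknown bone quality {label!r}; expected one of D1, D2, D3, D4"
        ) from None


def bone_quality_labels() -> list[str]:
    return ["D1", "D2", "D3", "D4"]


def graded_modulus(z, spec: BoneQualitySpec):
    """Young's modulus (GPa) at depth ``z`` (mm) past the
    cortical/transition interface.

    Constant cortical value for z <= 0, linear ramp across the transition
    zone, cancellous value beyond; continuous everywhere.  Accepts scalars
    or arrays.
    """
    import numpy as np

    z = np.asarray(z, dtype=float)
    t = np.clip(z / spec.transition_thickness, 0.0, 1.0)
    e = spec.e_cortical + (spec.e_cancellous - spec.e_cortical) * t
    return float(e) if e.ndim == 0 else e


@dataclass(frozen=True)
class OgdenParams:
    """First-order Ogden parameters for the periodontal ligament.

    Classical convention W = (mu1/alpha1) * (l1^a + l2^a + l3^a - 3) with
    ground-state shear modulus mu0 = mu1*alpha1/2; d1 = 0 means fully
    incompressible.
    """

    mu1: float = 0.006  # MPa
    alpha1: float = 29.8
    d1: float = 0.0  # 1/MPa

    def __post_init__(self) -> None:
        if self.mu1 * self.alpha1 <= 0:
            raise ValueError("mu1 * alpha1 must be positive")

    @property
    def shear_modulus(self) -> float:
        """Ground-state shear modulus mu0 (MPa)."""
        return 0.5 * self.mu1 * self.alpha1


PDL_OGDEN = OgdenParams()


def ogden_strain_energy(stretch: float, p: OgdenParams = PDL_OGDEN) -> float:
    """Strain energy density (MPa) along the incompressible uniaxial path
    (l, l^-1/2, l^-1/2)."""
    lam = float(stretch)
    if lam <= 0:
        raise ValueError("stretch must be positive")
    a = p.alpha1
    return (p.mu1 / a) * (lam**a + 2.0 * lam ** (-a / 2.0) - 3.0)


def ogden_uniaxial_stress(stretch, p: OgdenParams = PDL_OGDEN):
    """Uniaxial Cauchy (true) stress (MPa) of the incompressible
    first-order Ogden solid: sigma = mu1 * (l^a - l^(-a/2)).

    Zero at l = 1, strictly increasing, with small-strain Young's modulus
    3*mu0 = 3*mu1*alpha1/2.
    """
    import numpy as np

    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    a = p.alpha1
    sig = p.mu1 * (lam**a - lam ** (-a / 2.0))
    return float(sig) if sig.ndim == 0 else sig
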