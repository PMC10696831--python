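"""Method specifications, the combinatorial quantile-normalisation
family, and the pinned 16-method benchmark registry.

The combinatorial family follows a five-letter nomenclature: the first
letter says whether background adjustment is applied ('d') or not
('n'); the third letter says whether between-array quantile
normalisation treats Type I and II probes separately ('s'), together
('t'), or not at all ('n'); the fifth letter does the same for
dye-bias correction.  So e.g. ``nasen`` = no background, between-array
QN by type, no dye correction; ``nanet`` = dye correction pooled over
types only.  ``daten1`` and ``daten2`` share the letters d/t/n and
differ in whether the M and U signals are quantile-normalised as
separate matrices (variant 1) or pooled into a single pass (variant 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ..core import BetaMatrix, IntensityData, beta_from_intensities
from ..errors import ValidationError
from .between_array import funnorm_normalise, tost_normalise
from .quantile import background_equalise, dye_bias_correct, quantile_normalise
from .within_array import bmiq_normalise, noob_normalise, pbc_normalise, \
    swan_normalise

FAMILIES = ("raw", "combinatorial_qn", "swan", "bmiq", "pbc", "noob",
            "funnorm", "tost")


@dataclass(frozen=True)
class MethodSpec:
    """A resolvable normalisation strategy.

    For ``family='combinatorial_qn'`` the three step letters must all
    be set: ``background`` in {'d','n'}, ``between_array`` and
    ``dye_bias`` in {'s','t','n'}; ``variant`` distinguishes daten1
    (M/U normalised separately) from daten2 (pooled).
    """

    name: str
    family: str
    background: str | None = None
    between_array: str | None = None
    dye_bias: str | None = None
    variant: int | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}")
        if self.family == "combinatorial_qn":
            if self.background not in ("d", "n"):
                raise ValidationError("background must be 'd' or 'n'")
            if self.between_array not in ("s", "t", "n"):
                raise ValidationError("between_array must be 's','t','n'")
            if self.dye_bias not in ("s", "t", "n"):
                raise ValidationError("dye_bias must be 's','t','n'")

    def to_dict(self) -> dict:
        return {"name": self.name, "family": self.family,
                "background": self.background,
                "between_array": self.between_array,
                "dye_bias": self.dye_bias, "variant": self.variant}

    @classmethod
    def from_dict(cls, d: dict) -> "MethodSpec":
        return cls(**d)

    @property
    def is_within_array(self) -> bool:
        """True when the method uses only each sample's own values."""
        if self.family in ("raw", "swan", "bmiq", "pbc", "noob"):
            return True
        if self.family == "combinatorial_qn":
            return self.background != "d" and self.between_array == "n"
        return False


def apply_combinatorial_method(data: IntensityData, spec: MethodSpec,
                               offset: float = 100.0,
                               return_intensities: bool = False
                               ) -> BetaMatrix | IntensityData:
    """Compose the combinatorial pipeline: background equalisation if
    'd', then dye-bias correction ('s'/'t'), then between-array QN of
    the M and U matrices ('s' = by design type, 't' = one group), then
    betas.  ``return_intensities`` stops before the beta conversion and
    returns the normalised signal matrices instead."""
    if spec.family != "combinatorial_qn":
        raise ValidationError(f"{spec.name} is not a combinatorial method")
    if spec.background == "d":
        data = background_equalise(data)
    if spec.dye_bias in ("s", "t"):
        data = dye_bias_correct(data, mode=spec.dye_bias)
    if spec.between_array in ("s", "t"):
        if spec.between_array == "s":
            groups = data.annotation.table["design_type"]
        else:
            groups = None
        if spec.variant == 2:
            # pool M and U into one QN pass
            stacked = pd.concat(
                [data.meth,
                 data.unmeth.set_axis(data.unmeth.index + "__U", axis=0)],
                axis=0)
            if groups is not None:
                groups = pd.concat(
                    [groups, groups.set_axis(groups.index + "__U")])
            normed = quantile_normalise(stacked, groups)
            meth = normed.loc[data.meth.index]
            unmeth = normed.loc[data.unmeth.index + "__U"]
            unmeth.index = data.unmeth.index
            data = data.with_signal(meth, unmeth)
        else:
            data = data.with_signal(
                quantile_normalise(data.meth, groups),
                quantile_normalise(data.unmeth, groups))
    if return_intensities:
        return data
    return beta_from_intensities(data, offset=offset)


_COMBINATORIAL = [
    # (name, background, between_array, dye_bias, variant)
    ("nasen", "n", "s", "n", None),
    ("dasen", "d", "s", "n", None),
    ("naten", "n", "t", "n", None),
    ("daten1", "d", "t", "n", 1),
    ("daten2", "d", "t", "n", 2),
    ("nanet", "n", "n", "t", None),
    ("danet", "d", "n", "t", None),
    ("nanes", "n", "n", "s", None),
    ("danes", "d", "n", "s", None),
]

_NAMED = ["raw", "swan", "noob", "bmiq", "pbc", "tost", "funnorm"]


def registry_16_methods() -> list[MethodSpec]:
    """The pinned benchmark set of 16 strategies: raw data, the six
    named methods, and nine combinatorial quantile-normalisation
    variants."""
    specs = [MethodSpec(name=n, family=n if n != "raw" else "raw")
             for n in _NAMED]
    specs += [MethodSpec(name=n, family="combinatorial_qn", background=bg,
                         between_array=ba, dye_bias=dye, variant=var)
              for n, bg, ba, dye, var in _COMBINATORIAL]
    return specs


def get_method(name: str) -> MethodSpec:
    for spec in registry_16_methods():
        if spec.name == name:
            return spec
    raise ValidationError(
        f"unknown method {name!r}; registry: "
        + ", ".join(s.name for s in registry_16_methods()))


def normalise(data: IntensityData, method: MethodSpec | str,
              offset: float = 100.0) -> BetaMatrix:
    """Apply any registry method to intensity data, returning betas."""
    spec = get_method(method) if isinstance(method, str) else method
    if spec.family == "raw":
        return beta_from_intensities(data, offset=offset)
    if spec.family == "combinatorial_qn":
        return apply_combinatorial_method(data, spec, offset=offset)
    if spec.family == "swan":
        return swan_normalise(data, offset=offset)
    if spec.family == "noob":
        return beta_from_intensities(noob_normalise(data), offset=offset)
    if spec.family == "bmiq":
        return bmiq_normalise(beta_from_intensities(data, offset=offset))
    if spec.family == "pbc":
        return pbc_normalise(beta_from_intensities(data, offset=offset))
    if spec.family == "funnorm":
        return funnorm_normalise(data, offset=offset)
    if spec.family == "tost":
        return tost_normalise(data, offset=offset)
    raise ValidationError(f"no dispatch for family {spec.family!r}")
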