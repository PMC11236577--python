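"""Interface for the medial entorhinal cortex (mEC) PV-IN model.

The comparison model for the applied-current bistability analysis is a
published single-cell mEC fast-spiking interneuron model whose full
equation set is not reproduced here.  This module defines the plug-in
surface only: a parameter container with the same bounds checks as the
CA1 model, a registration hook for a user-supplied right-hand side
sourced from the original publication, and an explicit error until one
is provided.  Every CA1 analysis runs with this module disabled.

To enable it::

    from pvin import via_ref
    via_ref.register_ec_model(my_rhs)   # my_rhs(state, I_app_pA, params)

where ``my_rhs`` implements the published equations verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ECModelParameters", "ReferenceEquationsRequired",
           "register_ec_model", "ec_rhs", "is_registered"]


class ReferenceEquationsRequired(RuntimeError):
    """Raised when the mEC model is used without its published
    equations having been registered."""


@dataclass
class ECModelParameters:
    """Conductances/reversals of the mEC PV-IN model (user-supplied).

    ``provenance`` must name the source publication of the equations.
    """

    conductances_mS_cm2: dict = field(default_factory=dict)
    reversals_mV: dict = field(default_factory=dict)
    kinetic_constants: dict = field(default_factory=dict)
    C_M: float = 1.0
    area_cm2: float | None = None
    provenance: str = ""

    def validate(self) -> None:
        for name, g in self.conductances_mS_cm2.items():
            if g < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        if self.area_cm2 is not None and self.area_cm2 <= 0:
            raise ValueError("area must be > 0")
        if not self.provenance:
            raise ValueError("provenance (source publication) is required")

    @property
    def populated(self) -> bool:
        return bool(self.conductances_mS_cm2 and self.reversals_mV
                    and self.provenance)


_registered_rhs = None


def register_ec_model(rhs_fn) -> None:
    """Register the published mEC right-hand side
    ``rhs_fn(state, I_app_pA, params) -> dstate/dt``."""
    global _registered_rhs
    if not callable(rhs_fn):
        raise TypeError("rhs_fn must be callable")
    _registered_rhs = rhs_fn


def is_registered() -> bool:
    return _registered_rhs is not None


def ec_rhs(state, I_app_pA: float, params: ECModelParameters) -> np.ndarray:
    """Right-hand side of the mEC model.

    Raises :class:`ReferenceEquationsRequired` unless the published
    equations have been registered and the parameter set is populated
    from the source publication.
    """
    if _registered_rhs is None or not params.populated:
        raise ReferenceEquationsRequired(
            "reference equations required: the mEC PV-IN model's equations "
            "are not distributed with this package; populate "
            "ECModelParameters from the source publication and call "
            "register_ec_model() first")
    params.validate()
    return np.asarray(_registered_rhs(state, I_app_pA, params), dtype=float)
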