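"""Choosing a statistically appropriate fitting procedure for a design.

In a critical-speed/critical-power experiment exactly one of the three
variables — speed, time, distance — is fixed by the protocol; the other
two are measured (or derived) and carry error.  Regression is only valid
when the error-carrying variable sits on the vertical axis and the fixed
one on the horizontal axis.  That rule classifies every directed form of
the two-parameter model into one of three groups:

* ``WLS_APPROPRIATE`` — vertical axis measured with error, horizontal
  axis fixed: weighted least squares with inverse-variance weights on
  the vertical variable is the method of choice.
* ``WRONG_DEPENDENT`` — the fixed (error-free) variable sits on the
  vertical axis, so the loss is minimised along the wrong direction.
* ``ENDOGENOUS_NO_METHOD`` — both axes carry errors and those errors are
  correlated (e.g. distance error = speed x time error in a fixed-speed
  design); no standard regression method handles this, so the selector
  reports that none should be used.

For every design the six directed forms split exactly 2/2/2 across the
three groups.  One special case: at extremely high power on an ergometer
or when cycling outdoors, power itself becomes error-carrying and
geometric mean regression is the published recommendation; the selector
reports this and does not implement such a fit.

The selector is pure metadata: it never blocks a fit.  Running a
procedure it classifies as inappropriate is legitimate (that is how the
biases of such procedures are quantified), but every fit result should
carry the classification.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .fitting import Appropriateness, FittingProcedure, ModelVariant

__all__ = [
    "Variable",
    "DirectedForm",
    "Status",
    "ExperimentDesign",
    "FormAdvice",
    "Recommendation",
    "recommend",
    "classify_procedure",
]


class Variable(str, enum.Enum):
    SPEED = "speed"
    TIME = "time"
    DISTANCE = "distance"


class DirectedForm(str, enum.Enum):
    """The six directed rearrangements y(x) of the two-parameter model."""

    T_OF_S = "t(s)"
    D_OF_S = "d(s)"
    S_OF_T = "s(t)"
    D_OF_T = "d(t)"
    T_OF_D = "t(d)"
    S_OF_D = "s(d)"

    @property
    def vertical(self) -> Variable:
        return _AXES[self][0]

    @property
    def horizontal(self) -> Variable:
        return _AXES[self][1]

    @property
    def uses_inverse_form(self) -> bool:
        """True for t(d) and s(d): inverses of d(t) and d(s).

        Vertical-axis minimisation on an inverse form f^-1 is the same
        problem as horizontal-axis minimisation on f.
        """
        return self in (DirectedForm.T_OF_D, DirectedForm.S_OF_D)


_AXES = {
    DirectedForm.T_OF_S: (Variable.TIME, Variable.SPEED),
    DirectedForm.D_OF_S: (Variable.DISTANCE, Variable.SPEED),
    DirectedForm.S_OF_T: (Variable.SPEED, Variable.TIME),
    DirectedForm.D_OF_T: (Variable.DISTANCE, Variable.TIME),
    DirectedForm.T_OF_D: (Variable.TIME, Variable.DISTANCE),
    DirectedForm.S_OF_D: (Variable.SPEED, Variable.DISTANCE),
}


class Status(str, enum.Enum):
    WLS_APPROPRIATE = "wls_appropriate"
    GEOMETRIC_MEAN_SUGGESTED = "geometric_mean_suggested"
    WRONG_DEPENDENT = "wrong_dependent"
    ENDOGENOUS_NO_METHOD = "endogenous_no_method"


@dataclass(frozen=True)
class ExperimentDesign:
    """Which variable the protocol fixes, plus the extreme-power flag."""

    fixed_variable: Variable
    extreme_power_context: bool = False


@dataclass(frozen=True)
class FormAdvice:
    status: Status
    weight_target: Variable | None  # variable to weight for WLS entries
    uses_inverse_form: bool
    note: str = ""


@dataclass(frozen=True)
class Recommendation:
    design: ExperimentDesign
    advice: dict[DirectedForm, FormAdvice]

    def as_table(self) -> list[dict]:
        """Flat machine-readable listing, one row per directed form."""
        return [
            {
                "form": form.value,
                "status": adv.status.value,
                "weight_target": adv.weight_target.value if adv.weight_target else "",
                "inverse_form": adv.uses_inverse_form,
                "note": adv.note,
            }
            for form, adv in self.advice.items()
        ]


_GMR_NOTE = (
    "at extremely high ergometer power or when cycling outdoors, power is "
    "itself error-carrying: geometric mean regression is recommended "
    "(not implemented here)"
)


def recommend(design: ExperimentDesign) -> Recommendation:
    """Classify all six directed forms for a given experimental design.

    The rule: a form y(x) is WLS-appropriate iff x is the fixed variable
    (so y is measured with error); wrong-dependent iff y is the fixed
    variable; endogenous otherwise (both axes carry correlated errors).
    """
    advice: dict[DirectedForm, FormAdvice] = {}
    for form in DirectedForm:
        note = ""
        if form.horizontal is design.fixed_variable:
            status = Status.WLS_APPROPRIATE
            weight_target = form.vertical
            if design.extreme_power_context and design.fixed_variable is Variable.SPEED:
                status = Status.GEOMETRIC_MEAN_SUGGESTED
                note = _GMR_NOTE
        elif form.vertical is design.fixed_variable:
            status = Status.WRONG_DEPENDENT
            weight_target = None
            note = (
                f"{form.vertical.value} is fixed by the protocol and carries no "
                f"error; it must not be the dependent variable"
            )
        else:
            status = Status.ENDOGENOUS_NO_METHOD
            weight_target = None
            note = (
                "both axes carry correlated errors; no regression method "
                "handles this case"
            )
        if form.uses_inverse_form and not note:
            note = "inverse form: vertical-axis fit equals horizontal-axis fit on its inverse"
        advice[form] = FormAdvice(
            status=status,
            weight_target=weight_target,
            uses_inverse_form=form.uses_inverse_form,
            note=note,
        )
    return Recommendation(design=design, advice=advice)


_VARIANT_TO_FORM = {
    ModelVariant.T_OF_S: DirectedForm.T_OF_S,
    ModelVariant.D_OF_S: DirectedForm.D_OF_S,
    ModelVariant.S_OF_T: DirectedForm.S_OF_T,
    ModelVariant.D_OF_T: DirectedForm.D_OF_T,
}

_STATUS_TO_APPROPRIATENESS = {
    Status.WLS_APPROPRIATE: Appropriateness.APPROPRIATE,
    Status.GEOMETRIC_MEAN_SUGGESTED: Appropriateness.APPROPRIATE,
    Status.WRONG_DEPENDENT: Appropriateness.WRONG_DEPENDENT,
    Status.ENDOGENOUS_NO_METHOD: Appropriateness.ENDOGENOUS,
}


def classify_procedure(
    procedure: FittingProcedure, design: ExperimentDesign
) -> Appropriateness:
    """Appropriateness of one of the four fittable variants under a design."""
    rec = recommend(design)
    status = rec.advice[_VARIANT_TO_FORM[procedure.variant]].status
    return _STATUS_TO_APPROPRIATENESS[status]
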