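"""Movement protocol definitions for the low back testing session.

The study protocol consists of six trunk movements performed while standing
or seated, each as a block of repetitions to a prescribed fraction of the
participant's end range.  Forward flexion is performed submaximally for the
first two repetitions (50% of end range) with a single final repetition to
100%; extension is capped at ~50% of end range throughout to protect the
sensing elements; lateral bending and seated rotation go to end range on
each side.
"""

from __future__ import annotations

from enum import Enum

from pydantic import BaseModel, ConfigDict, model_validator

from .errors import ParameterError


class Movement(str, Enum):
    """The six low back movement directions tested."""

    FORWARD_FLEXION = "forward_flexion"
    EXTENSION = "extension"
    LEFT_LATERAL_BEND = "left_lateral_bend"
    RIGHT_LATERAL_BEND = "right_lateral_bend"
    LEFT_ROTATION = "left_rotation"
    RIGHT_ROTATION = "right_rotation"


#: Movements whose normalized kinematic trace is multiplied by -1 so that the
#: primary movement direction reads positive (mirrors the study's processing).
DEFAULT_FLIP_SET = frozenset(
    {Movement.FORWARD_FLEXION, Movement.LEFT_LATERAL_BEND, Movement.RIGHT_ROTATION}
)

#: Index of the Euler component (x, y, z) carrying each movement's primary
#: plane: x = flexion/extension about ML, y = axial rotation about SI,
#: z = lateral bend about PA.
MOVEMENT_PRIMARY_COMPONENT: dict[Movement, int] = {
    Movement.FORWARD_FLEXION: 0,
    Movement.EXTENSION: 0,
    Movement.LEFT_LATERAL_BEND: 2,
    Movement.RIGHT_LATERAL_BEND: 2,
    Movement.LEFT_ROTATION: 1,
    Movement.RIGHT_ROTATION: 1,
}

#: Signed rotation sense of each movement about its primary axis in the lab
#: frame (X = subject-right, Y = up, Z = posterior).  Chosen so that exactly
#: the movements in DEFAULT_FLIP_SET trace negative raw angles; left/right
#: movement pairs are mirror-opposite.
MOVEMENT_AXIS_SIGN: dict[Movement, float] = {
    Movement.FORWARD_FLEXION: -1.0,
    Movement.EXTENSION: +1.0,
    Movement.LEFT_LATERAL_BEND: -1.0,
    Movement.RIGHT_LATERAL_BEND: +1.0,
    Movement.LEFT_ROTATION: +1.0,
    Movement.RIGHT_ROTATION: -1.0,
}


class MovementProtocolEntry(BaseModel):
    """One movement block of the testing protocol.

    Parameters
    ----------
    movement
        Movement direction.
    position
        Body position during the block ("standing" or "seated").
    repetitions
        Number of repetitions, >= 1.
    amplitude_fractions
        Per-repetition peak amplitude as a fraction of end range, each in
        (0, 1]; must have one entry per repetition.
    end_range_deg
        The participant's end range of motion for this movement, degrees.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    movement: Movement
    position: str = "standing"
    repetitions: int = 3
    amplitude_fractions: tuple[float, ...] = (1.0, 1.0, 1.0)
    end_range_deg: float = 30.0

    @model_validator(mode="after")
    def _check(self) -> "MovementProtocolEntry":
        if self.repetitions < 1:
            raise ParameterError("repetitions must be >= 1")
        if len(self.amplitude_fractions) != self.repetitions:
            raise ParameterError(
                "amplitude_fractions must have one entry per repetition "
                f"({len(self.amplitude_fractions)} != {self.repetitions})"
            )
        if not all(0.0 < f <= 1.0 for f in self.amplitude_fractions):
            raise ParameterError("amplitude fractions must lie in (0, 1]")
        if self.position not in ("standing", "seated"):
            raise ParameterError(f"unknown position {self.position!r}")
        if not self.end_range_deg > 0:
            raise ParameterError("end_range_deg must be positive")
        return self


def default_protocol() -> list[MovementProtocolEntry]:
    """The study's movement protocol.

    Repetition counts and amplitude fractions follow the testing protocol;
    end ranges are nominal healthy-adult lumbar ranges of motion (the study
    does not report measured end ranges): flexion 50 deg, extension 25 deg,
    lateral bend 25 deg, seated axial rotation 35 deg.
    """
    bend = dict(position="standing", repetitions=3,
                amplitude_fractions=(1.0, 1.0, 1.0), end_range_deg=25.0)
    rot = dict(position="seated", repetitions=3,
               amplitude_fractions=(1.0, 1.0, 1.0), end_range_deg=35.0)
    return [
        MovementProtocolEntry(movement=Movement.FORWARD_FLEXION, position="standing",
                              repetitions=3, amplitude_fractions=(0.5, 0.5, 1.0),
                              end_range_deg=50.0),
        MovementProtocolEntry(movement=Movement.EXTENSION, position="standing",
                              repetitions=3, amplitude_fractions=(0.5, 0.5, 0.5),
                              end_range_deg=25.0),
        MovementProtocolEntry(movement=Movement.LEFT_LATERAL_BEND, **bend),
        MovementProtocolEntry(movement=Movement.RIGHT_LATERAL_BEND, **bend),
        MovementProtocolEntry(movement=Movement.LEFT_ROTATION, **rot),
        MovementProtocolEntry(movement=Movement.RIGHT_ROTATION, **rot),
    ]
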