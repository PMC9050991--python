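"""PI voltage controller and the target-temperature ramp protocol.

The generator regulates the RMS electrode voltage with a proportional-
integral law on the tip-temperature error,

    V_RMS = K_p * (T_target - T_tip) + K_i * integral (T_target - T_tip) dt,

clamped to [0, v_max] with the integral frozen while the clamp is active
(anti-windup).  The clinical protocol is reported as two durations: total
time above 60 °C and time at the 90 °C target.  The simulated schedule holds
the target at 60 °C until the tip first reaches it, ramps linearly from 60
to 90 °C over the difference of the two durations, then holds 90 °C for the
reported time at 90 °C.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ProtocolError(ValueError):
    """Raised for inconsistent ablation protocols."""


@dataclass(frozen=True)
class AblationProtocol:
    """Reported intervention parameters and the derived target schedule.

    ``time_over_60_s`` is the total time the applicator spent above 60 °C and
    must include ``time_at_90_s``; the ramp from 60 to 90 °C takes their
    difference (zero difference means an immediate 90 °C target).
    """

    electrode_length_mm: float
    time_over_60_s: float
    time_at_90_s: float
    start_target_C: float = 60.0
    end_target_C: float = 90.0

    def __post_init__(self):
        if self.electrode_length_mm <= 0:
            raise ProtocolError("electrode_length_mm must be positive")
        if self.time_at_90_s < 0:
            raise ProtocolError("time_at_90_s must be >= 0")
        if self.time_over_60_s < self.time_at_90_s:
            raise ProtocolError(
                "time_over_60_s must be >= time_at_90_s "
                f"(got {self.time_over_60_s} < {self.time_at_90_s})"
            )

    @classmethod
    def from_minutes(
        cls, electrode_length_cm: float, time_over_60_min: float, time_at_90_min: float
    ) -> "AblationProtocol":
        """Build from the units the interventions are reported in."""
        return cls(
            electrode_length_mm=10.0 * electrode_length_cm,
            time_over_60_s=60.0 * time_over_60_min,
            time_at_90_s=60.0 * time_at_90_min,
        )

    @property
    def ramp_s(self) -> float:
        return self.time_over_60_s - self.time_at_90_s

    @property
    def schedule_end_s(self) -> float:
        return self.time_over_60_s

    def target_temperature(self, t_since_60_s: float) -> float | None:
        """Target at ``t`` seconds after the 60 °C-reached event.

        Negative times (event not yet reached) return the 60 °C hold value;
        times beyond the schedule end return ``None`` as the stop signal.
        """
        if t_since_60_s < 0:
            return self.start_target_C
        if t_since_60_s >= self.schedule_end_s:
            return None
        if t_since_60_s < self.ramp_s:
            frac = t_since_60_s / self.ramp_s
            return self.start_target_C + (self.end_target_C - self.start_target_C) * frac
        return self.end_target_C


def target_temperature(t_since_60_s: float, protocol: AblationProtocol) -> float | None:
    return protocol.target_temperature(t_since_60_s)


@dataclass
class PIController:
    """Discrete PI law with trapezoidal error integration and anti-windup."""

    kp_V_per_K: float = 1.15
    ki_V_per_Ks: float = 0.06
    v_max_V: float = 100.0
    integral_Ks: float = 0.0
    v_rms_V: float = 0.0
    _prev_error_K: float | None = field(default=None, repr=False)

    def reset(self) -> None:
        self.integral_Ks = 0.0
        self.v_rms_V = 0.0
        self._prev_error_K = None

    def update(self, tip_T_C: float, target_T_C: float, dt_s: float) -> float:
        """Advance one step; returns the clamped V_RMS in volts."""
        if dt_s <= 0:
            raise ValueError("dt_s must be positive")
        error = target_T_C - tip_T_C
        prev = self._prev_error_K if self._prev_error_K is not None else error
        candidate = self.integral_Ks + 0.5 * (error + prev) * dt_s
        v = self.kp_V_per_K * error + self.ki_V_per_Ks * candidate
        if 0.0 <= v <= self.v_max_V:
            self.integral_Ks = candidate  # accept; clamp inactive
        else:
            v = min(max(v, 0.0), self.v_max_V)  # clamp, freeze integral
        self._prev_error_K = error
        self.v_rms_V = v
        return v


def pi_update(ctrl: PIController, tip_T_C: float, target_T_C: float, dt_s: float) -> float:
    return ctrl.update(tip_T_C, target_T_C, dt_s)
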