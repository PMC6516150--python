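"""Unit conversion constants.

Two mmHg conversion factors coexist on purpose. Circumferential wall stress
in pressure myography is reported in CGS units using the rounded factor
1 mmHg = 133.4e3 dyn/cm^2, the convention of the passive-mechanics
literature this package follows. The wire-myography Laplace isobar uses SI
(1 mmHg = 133.322 Pa); wall tension in N/m is numerically identical to
mN/mm, the myograph's native unit.
"""

#: 1 mmHg in dyn/cm^2 (CGS), rounded as conventionally printed.
MMHG_TO_DYN_PER_CM2 = 133.4e3

#: 1 mmHg in Pa (SI).
MMHG_TO_PA = 133.322


def laplace_tension_coefficient(pressure_mmhg: float) -> float:
    """Slope of the Laplace isobar T = P*d/2 in (mN/mm) per um.

    Wall tension of a pressurized thin-walled cylinder is T = P*r = P*d/2
    (force per unit vessel length). With P in Pa and d in m, T is in
    N/m = mN/mm, so for d expressed in um the isobar through the origin of
    the diameter-tension plane has slope ``P[Pa] * 1e-6 / 2``.
    """
    return pressure_mmhg * MMHG_TO_PA * 1e-6 / 2.0
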