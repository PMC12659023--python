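"""Package-wide unit conventions and conversion constants.

Internal units: length Å, time ps, charge e (elementary charge),
voltage mV.  Derived reporting units: current nA, water flux
molecules/ns, conductance nS, conductivity S/m, concentration mol/L.
"""

#: Elementary charge in coulombs (2019 SI exact value).
E_CHARGE_C = 1.602176634e-19

#: Avogadro constant, 1/mol (2019 SI exact value).
N_AVOGADRO = 6.02214076e23

#: 1 e/ps expressed in nanoamperes.
E_PER_PS_TO_NA = E_CHARGE_C * 1e12 * 1e9  # = 160.2176634

#: 1 molecule/ps expressed in molecules/ns.
PER_PS_TO_PER_NS = 1e3

#: Number density 1/Å³ expressed in mol/L.
PER_A3_TO_MOL_PER_L = 1e27 / N_AVOGADRO

#: Conductivity unit e/(ps·mV·Å) expressed in S/m.
#: e/ps = E_CHARGE_C*1e12 A;  1/mV = 1e3/V;  1/Å = 1e10/m.
COND_TO_S_PER_M = E_CHARGE_C * 1e12 * 1e3 * 1e10  # = 1.602176634e6

#: Conductance nA/mV expressed in nS (nA/V).
NA_PER_MV_TO_NS = 1e3

#: Geometry factor for sigma = G·Lz/(Lx·Ly): nS·Å/Å² expressed in S/m.
NS_PER_A_TO_S_PER_M = 1e-9 * 1e-10 / 1e-20  # = 10.0
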