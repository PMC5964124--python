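"""Nearest-neighbor duplex thermodynamics for short DNA oligos.

Melting temperature and duplex formation free energy are computed with the
SantaLucia (1998) unified nearest-neighbor parameter set.  The parameter
table is embedded here under a version identifier (:data:`TABLE_ID`) so that
every annotation a panel carries is bit-reproducible and auditable.

Conventions
-----------
* ΔH in kcal/mol, ΔS in cal/(mol·K); both refer to duplex *formation*
  (negative ΔH = exothermic, more negative ΔG°37 = more stable duplex).
* Tm uses the two-state model for non-self-complementary duplexes with
  equimolar strands, ``Tm = ΔH·1000 / (ΔS + R·ln(CT/4)) − 273.15``,
  where CT is the total single-strand concentration, plus the SantaLucia
  (1998) entropic monovalent-salt correction
  ``ΔS(Na+) = ΔS(1M) + 0.368 · (N−1) · ln[Na+]``.
* ΔG°37 is reported at the 1 M NaCl reference state (no salt correction),
  which is how these tables are tabulated and compared in practice.
"""

from __future__ import annotations

import math

from .errors import ValidationError
from .sequtil import reverse_complement, validate_dna

#: Identifier of the parameter set; recorded in run manifests.
TABLE_ID = "santalucia-1998-unified"

#: Gas constant, cal/(mol·K).
R_GAS = 1.987

# The ten unique stacks; the remaining six follow by reverse-complement
# symmetry (filled in below).  Values: (ΔH kcal/mol, ΔS cal/mol/K).
_NN_CORE = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}

NN_PARAMS: dict[str, tuple[float, float]] = dict(_NN_CORE)
for _stack, _hs in _NN_CORE.items():
    NN_PARAMS.setdefault(reverse_complement(_stack), _hs)

#: Duplex initiation terms for a terminal G·C / A·T pair.
INIT_GC = (0.1, -2.8)
INIT_AT = (2.3, 4.1)

_MIN_LEN = 8


def duplex_enthalpy_entropy(sequence: str) -> tuple[float, float]:
    """Total (ΔH, ΔS) of duplex formation: stack sum plus both initiation terms."""
    seq = validate_dna(sequence, name="sequence", min_length=_MIN_LEN)
    dh, ds = 0.0, 0.0
    for i in range(len(seq) - 1):
        h, s = NN_PARAMS[seq[i:i + 2]]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = INIT_GC if terminal in "GC" else INIT_AT
        dh += h
        ds += s
    return dh, ds


def melting_temperature(sequence: str, salt_mM: float = 50.0,
                        oligo_conc_nM: float = 5.05) -> float:
    """Two-state nearest-neighbor Tm in °C.

    Parameters
    ----------
    salt_mM : monovalent cation concentration (Na+ equivalent), millimolar.
    oligo_conc_nM : total single-strand concentration CT, nanomolar.  For a
        duplex pool with both strands equimolar this is twice the per-strand
        concentration; the default matches a 5.05 nM pooled oligo.
    """
    if salt_mM <= 0 or oligo_conc_nM <= 0:
        raise ValidationError("salt_mM and oligo_conc_nM must be positive")
    seq = validate_dna(sequence, name="sequence", min_length=_MIN_LEN)
    dh, ds = duplex_enthalpy_entropy(seq)
    ds += 0.368 * (len(seq) - 1) * math.log(salt_mM / 1000.0)
    ct = oligo_conc_nM * 1e-9
    return dh * 1000.0 / (ds + R_GAS * math.log(ct / 4.0)) - 273.15


def duplex_delta_g(sequence: str, temp_celsius: float = 37.0) -> float:
    """ΔG° of duplex formation at ``temp_celsius``, kcal/mol (1 M NaCl reference).

    ΔG = ΔH − T·ΔS; more negative means a more thermostable duplex, which in
    pooled-oligo libraries anneals more efficiently and yields more reads.
    """
    dh, ds = duplex_enthalpy_entropy(sequence)
    t_kelvin = temp_celsius + 273.15
    return dh - t_kelvin * ds / 1000.0
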