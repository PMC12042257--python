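"""Shared test oracle: peptide molecular formulas by pure arithmetic.

Independent of the package's chemistry code: sums textbook free-residue
formulas and subtracts one water per peptide bond, formatting the result
in Hill order (C, H, then alphabetical) for comparison with RDKit's
formula strings.
"""

import re

AA_FORMULAS = {
    "G": "C2H5NO2", "A": "C3H7NO2", "R": "C6H14N4O2", "N": "C4H8N2O3",
    "D": "C4H7NO4", "C": "C3H7NO2S", "E": "C5H9NO4", "Q": "C5H10N2O3",
    "H": "C6H9N3O2", "I": "C6H13NO2", "L": "C6H13NO2", "K": "C6H14N2O2",
    "M": "C5H11NO2S", "F": "C9H11NO2", "P": "C5H9NO2", "S": "C3H7NO3",
    "T": "C4H9NO3", "W": "C11H12N2O2", "Y": "C9H11NO3", "V": "C5H11NO2",
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def counts(formula: str) -> dict:
    return {el: int(n) if n else 1 for el, n in _FORMULA_RE.findall(formula) if el}


def hill(count: dict) -> str:
    order = ["C", "H"] + sorted(k for k in count if k not in ("C", "H"))
    return "".join(
        f"{el}{count[el] if count[el] > 1 else ''}" for el in order if count.get(el)
    )


def peptide_formula(seq: str) -> str:
    total: dict = {}
    for code in seq:
        for el, n in counts(AA_FORMULAS[code]).items():
            total[el] = total.get(el, 0) + n
    total["H"] -= 2 * (len(seq) - 1)
    total["O"] -= len(seq) - 1
    return hill(total)
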