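"""Physical constants and atomic masses used throughout the package."""

#: Gas constant in kJ/(mol·K)
R_KJ_MOL_K = 8.31446e-3

#: Avogadro constant in mol^-1 (exact, SI 2019)
AVOGADRO = 6.02214076e23

#: IUPAC 2021 standard atomic weights for the elements common in
#: pharmaceutical organic crystals.  Other elements fall back to gemmi's
#: built-in table at the call site.
ATOMIC_WEIGHTS = {
    "H": 1.008,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998403163,
    "Na": 22.98976928,
    "Mg": 24.305,
    "P": 30.973761998,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.0983,
    "Ca": 40.078,
    "Br": 79.904,
    "I": 126.90447,
}


def atomic_weight(symbol: str) -> float:
    """Standard atomic weight in g/mol for an element symbol."""
    try:
        return ATOMIC_WEIGHTS[symbol]
    except KeyError:
        import gemmi

        el = gemmi.Element(symbol)
        if el.weight <= 0 or el.name == "X":
            raise ValueError(f"unknown element symbol: {symbol!r}") from None
        return el.weight
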