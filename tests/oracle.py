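"""Independent brute-force speciation oracle for cross-checking the solver.

Solves the two mass balances by nested bracketing on log10 of the free
concentrations, written without reference to the package's Newton path.
"""

import numpy as np
from scipy.optimize import brentq

LOG_FLOOR = -40.0


def oracle_speciate(species, total_M, total_L, pH):
    """Free and species concentrations by nested log10 bracketing.

    ``species`` is a list of (name, m, l, h, log_beta) tuples.
    Returns (free_M, free_L, {name: conc}).
    """

    def concs(logM, logL):
        out = {}
        for name, m, l, h, lb in species:
            out[name] = 10.0 ** (lb + m * logM + l * logL - h * pH)
        return out

    def calc_totals(logM, logL):
        c = concs(logM, logL)
        tm = 10.0 ** logM + sum(m * c[n] for n, m, l, h, lb in species)
        tl = 10.0 ** logL + sum(l * c[n] for n, m, l, h, lb in species)
        return tm, tl

    def solve_logL(logM):
        if total_L <= 0:
            return LOG_FLOOR
        f = lambda logL: calc_totals(logM, logL)[1] - total_L
        if f(LOG_FLOOR) >= 0:
            return LOG_FLOOR
        return brentq(f, LOG_FLOOR, np.log10(total_L), xtol=1e-14, rtol=8.9e-16)

    if total_M <= 0:
        logM = LOG_FLOOR
        logL = solve_logL(logM)
    else:
        g = lambda logM: calc_totals(logM, solve_logL(logM))[0] - total_M
        if g(LOG_FLOOR) >= 0:
            logM = LOG_FLOOR
        else:
            logM = brentq(g, LOG_FLOOR, np.log10(total_M), xtol=1e-14, rtol=8.9e-16)
        logL = solve_logL(logM)
    return 10.0 ** logM, 10.0 ** logL, concs(logM, logL)


def as_tuples(system):
    """Convert a ChemicalSystem's species to the oracle's tuple form."""
    return [(sp.name, sp.n_metal, sp.n_ligand, sp.n_proton, sp.log_beta)
            for sp in system.species]
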