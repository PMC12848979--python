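"""Per-contact free energies and totals for AIP contact lists.

Model
-----
A single surface-site contact between AIPs i and j has association constant

    K_ij = 1/2 exp(-(eps_i*eps_j + E_vdW)/RT),      eps_i*eps_j <= 0
    K_ij = K_vdW = 1/2 exp(-E_vdW/RT),              eps_i*eps_j > 0

(repulsive polar pairs are clamped to the nonpolar constant: dipoles can
reorient to avoid repulsion).  E_vdW = -5.6 kJ/mol is the free energy of a
nonpolar van der Waals surface contact.

The free energy of an AIP in the bound state is

    dG_B(i) = dG_B(j) = RT ln[(sqrt(1+8*theta)-1)/(4*theta)]
            + RT ln[(sqrt(1+4*theta*K_tot)-1)/(2*theta*K_tot)]

with K_tot = K_ij + K_vdW and theta the total AIP density of the solvent.
The first term is solute-independent and cancels in any contact free
energy; the second is RT ln of the free-site fraction of a pairing
equilibrium at density theta with constant K_tot.

Solvation of an AIP in the free state treats the liquid as a Boltzmann
ensemble of pairwise site contacts.  The solvent's own sites compete for
each other: their free fractions phi_k solve the self-consistent
speciation

    phi_k = 1 / (1 + theta * sum_l x_l * phi_l * (K_kl + K_vdW))

and a solute site i is then solvated against the *available* solvent
surface,

    dG_S(i) = RT ln[(sqrt(1+8*theta)-1)/(4*theta)]
            + RT ln[ 1 / (1 + theta * sum_k x_k * phi_k * (K_ik + K_vdW)) ].

Strong solvent self-association (water) leaves few free sites, which
weakens the solvation of weakly polar solute sites and produces the
hydrophobic driving force: nonpolar contacts are net attractive even
though each is worth little.

Each contact then contributes

    ddG(i,j) = f * [dG_B(i) + dG_B(j) - dG_S(i) - dG_S(j)]

with f = min(f_i, f_j), and the binding free energy is the plain sum
-RT ln K = dG_calc = sum ddG(i,j).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np

from .aip_core import Constants, ContactRecord, SolventModel, DEFAULT_CONSTANTS

__all__ = [
    "EnergyBreakdown",
    "k_vdw",
    "k_ij",
    "solvent_free_fractions",
    "dg_bound",
    "dg_solvation",
    "contact_ddG",
    "total_binding_energy",
    "load_solvent_config",
    "write_solvent_config",
    "water",
]


@dataclass
class EnergyBreakdown:
    contacts: list[ContactRecord]
    total_dG_calc: float
    association_constant: float


def k_vdw(T: float = 298.0, *, e_vdw: float = DEFAULT_CONSTANTS.e_vdw,
          R: float = DEFAULT_CONSTANTS.gas_constant) -> float:
    """Association constant of a nonpolar van der Waals surface contact."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return 0.5 * math.exp(-e_vdw / (R * T))


def k_ij(eps_i: float, eps_j: float, T: float = 298.0, *,
         e_vdw: float = DEFAULT_CONSTANTS.e_vdw,
         R: float = DEFAULT_CONSTANTS.gas_constant) -> float:
    """Association constant of an AIP-AIP contact (clamped when repulsive)."""
    product = eps_i * eps_j
    if product > 0:
        return k_vdw(T, e_vdw=e_vdw, R=R)
    return 0.5 * math.exp(-(product + e_vdw) / (R * T))


def _log_checked(x: float, what: str) -> float:
    if not math.isfinite(x) or x <= 0:
        raise ValueError(f"non-positive logarithm argument in {what}: {x}")
    return math.log(x)


def _confinement_term(theta: float, rt: float) -> float:
    return rt * _log_checked((math.sqrt(1 + 8 * theta) - 1) / (4 * theta),
                             "confinement term")


def _pairing_term(K_tot: float, theta: float, rt: float) -> float:
    return rt * _log_checked(
        (math.sqrt(1 + 4 * theta * K_tot) - 1) / (2 * theta * K_tot),
        "pairing term")


def solvent_free_fractions(solvent: SolventModel,
                           constants: Constants = DEFAULT_CONSTANTS,
                           tol: float = 1e-14, max_iter: int = 100_000) -> np.ndarray:
    """Self-consistent free-site fractions of the solvent ensemble."""
    eps = np.array([e for e, _ in solvent.solvent_aips], dtype=float)
    x = np.array([f for _, f in solvent.solvent_aips], dtype=float)
    T = solvent.temperature
    kv = k_vdw(T, e_vdw=constants.e_vdw, R=constants.gas_constant)
    Kt = np.empty((len(eps), len(eps)))
    for a in range(len(eps)):
        for b in range(len(eps)):
            Kt[a, b] = k_ij(eps[a], eps[b], T, e_vdw=constants.e_vdw,
                            R=constants.gas_constant) + kv
    phi = np.full(len(eps), 0.5)
    for _ in range(max_iter):
        new = 1.0 / (1.0 + solvent.theta * (Kt @ (x * phi)))
        if float(np.max(np.abs(new - phi))) < tol:
            return new
        phi = 0.5 * (phi + new)
    return phi


def dg_bound(eps_i: float, eps_j: float, solvent: SolventModel,
             constants: Constants = DEFAULT_CONSTANTS) -> float:
    """Free energy of either AIP of a bound contact (the two are equal)."""
    T = solvent.temperature
    rt = constants.gas_constant * T
    kv = k_vdw(T, e_vdw=constants.e_vdw, R=constants.gas_constant)
    K_tot = k_ij(eps_i, eps_j, T, e_vdw=constants.e_vdw,
                 R=constants.gas_constant) + kv
    return _confinement_term(solvent.theta, rt) + _pairing_term(K_tot, solvent.theta, rt)


def dg_solvation(eps_i: float, solvent: SolventModel,
                 constants: Constants = DEFAULT_CONSTANTS,
                 _phi: np.ndarray | None = None) -> float:
    """Solvation free energy of a single AIP in the free state.

    The solute site competes for solvent sites already engaged in
    solvent-solvent contacts; only the free fraction of each solvent site
    type is available to it.
    """
    T = solvent.temperature
    rt = constants.gas_constant * T
    kv = k_vdw(T, e_vdw=constants.e_vdw, R=constants.gas_constant)
    phi = solvent_free_fractions(solvent, constants) if _phi is None else _phi
    K_avail = 0.0
    for (eps_k, x_k), phi_k in zip(solvent.solvent_aips, phi):
        K_avail += x_k * phi_k * (k_ij(eps_i, eps_k, T, e_vdw=constants.e_vdw,
                                       R=constants.gas_constant) + kv)
    return _confinement_term(solvent.theta, rt) + rt * _log_checked(
        1.0 / (1.0 + solvent.theta * K_avail), "solvation term")


def contact_ddG(contact: ContactRecord, solvent: SolventModel,
                constants: Constants = DEFAULT_CONSTANTS,
                _phi: np.ndarray | None = None) -> ContactRecord:
    """Return a copy of ``contact`` with ddG and its decomposition filled."""
    ei = contact.ligand_aip.epsilon
    ej = contact.protein_aip.epsilon
    gb = dg_bound(ei, ej, solvent, constants)
    phi = solvent_free_fractions(solvent, constants) if _phi is None else _phi
    gsi = dg_solvation(ei, solvent, constants, _phi=phi)
    gsj = dg_solvation(ej, solvent, constants, _phi=phi)
    ddg = contact.f_effective * (gb + gb - gsi - gsj)
    return replace(contact, ddG=ddg, decomposition=(gb, gb, gsi, gsj))


def total_binding_energy(contacts: list[ContactRecord], solvent: SolventModel,
                         constants: Constants = DEFAULT_CONSTANTS) -> EnergyBreakdown:
    """Score every contact and sum to the binding free energy.

    Contacts whose ddG is unset are scored first.  Returns the scored
    contacts, dG_calc = sum f*ddG(i,j) and K = exp(-dG_calc / RT).
    """
    phi = solvent_free_fractions(solvent, constants)
    scored = [c if c.ddG is not None else contact_ddG(c, solvent, constants, _phi=phi)
              for c in contacts]
    total = float(sum(c.ddG for c in scored))
    rt = constants.gas_constant * solvent.temperature
    return EnergyBreakdown(contacts=scored, total_dG_calc=total,
                           association_constant=math.exp(-total / rt))


# ---------------------------------------------------------------------------
# Solvent config I/O (key-value header + site table)
# ---------------------------------------------------------------------------

def load_solvent_config(source) -> SolventModel:
    """Read a solvent model from structured text.

    Format: comment lines start with '#'; ``name``, ``theta`` and
    ``temperature`` are key-value lines; each ``site <epsilon>
    <mole_fraction>`` line adds one solvent AIP type.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    name, theta, temperature = "", None, 298.0
    sites: list[tuple[float, float]] = []
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        key = fields[0].lower()
        try:
            if key == "name":
                name = " ".join(fields[1:])
            elif key == "theta":
                theta = float(fields[1])
            elif key == "temperature":
                temperature = float(fields[1])
            elif key == "site":
                sites.append((float(fields[1]), float(fields[2])))
            else:
                raise ValueError(f"unknown key {key!r}")
        except (IndexError, ValueError) as exc:
            raise ValueError(f"solvent config line {ln}: {raw!r}: {exc}") from exc
    if theta is None:
        raise ValueError("solvent config missing 'theta'")
    return SolventModel(theta=theta, solvent_aips=sites,
                        temperature=temperature, name=name)


def write_solvent_config(solvent: SolventModel, path=None) -> str:
    lines = [f"name {solvent.name}" if solvent.name else "# unnamed solvent",
             f"theta {solvent.theta!r}",
             f"temperature {solvent.temperature!r}",
             "# site  epsilon  mole_fraction"]
    for eps, x in solvent.solvent_aips:
        lines.append(f"site {eps!r} {x!r}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def water() -> SolventModel:
    """The shipped water AIP ensemble (see data file for provenance)."""
    ref = resources.files("aipmap.data").joinpath("water_aip.solvent")
    return load_solvent_config(ref.open("r"))
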