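"""Reference worked example: thrombin-inhibitor binding decomposition.

Published snapshot-averaged MM/PBSA component means (kcal/mol) for the
human alpha-thrombin / macrocyclic-inhibitor complex (PDB entry 1NM6)
evaluated under an unpolarized force-field charge model ("AMBER") and a
polarized protein-specific charge model ("PPC"), in the mixed
charge-set x trajectory design: each row is (electrostatic, van der
Waals, polar solvation, nonpolar solvation, entropy term).  The entropy
term is recorded positive when entropy opposes binding, so that the
binding free energy is the plain sum of the five entries.

Only the component means are stored; totals and sub-totals are assembled
at run time by :func:`polarbind.mmpbsa.assemble_total` — the table is the
package's standard worked example for the assembly identities.
The experimental binding free energy of this complex, derived from the
inhibition constant, is -13.70 kcal/mol.
"""

#: (charge model, trajectory) -> component means, kcal/mol
THROMBIN_L86_COMPONENTS = {
    ("AMBER", "AMBER"): {"ele": -15.01, "vdw": -53.59, "pol": 47.00,
                         "nonpol": -5.19, "tds": 23.10},
    ("PPC", "PPC"): {"ele": -27.76, "vdw": -52.42, "pol": 47.90,
                     "nonpol": -4.95, "tds": 24.19},
    ("AMBER", "PPC"): {"ele": -18.75, "vdw": -52.42, "pol": 46.85,
                       "nonpol": -4.95, "tds": 25.60},
    ("PPC", "AMBER"): {"ele": -15.53, "vdw": -53.59, "pol": 52.15,
                       "nonpol": -5.19, "tds": 21.75},
    ("AMBER", "X-ray"): {"ele": -22.18, "vdw": -62.18, "pol": 65.00,
                         "nonpol": -5.26, "tds": 22.42},
    ("PPC", "X-ray"): {"ele": -31.81, "vdw": -62.18, "pol": 59.95,
                       "nonpol": -5.26, "tds": 25.26},
}

#: experimental binding free energy (from K_i), kcal/mol
EXPERIMENTAL_DG = -13.70
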