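"""Default per-residue amino-acid property table.

The property encoder represents each residue by a vector of physicochemical
descriptors.  The default table bundles 48 properties: 28 widely used
literature scales (hydropathy, hydrophobicity, polarity, size, secondary
structure propensity, atom composition, chemical-class indicators) plus the
20 residue-identity indicators.  The set is a package default, not a claim
about any particular published 48-property selection; callers can substitute
their own table (see :class:`bindres.encode.PropertyTable`).

All scales are ordered by :data:`AA_ORDER` = ``ARNDCQEGHILKMFPSTWYV``, the
same amino-acid ordering used for PSSM columns and BLOSUM62 rows throughout
the package.
"""

from __future__ import annotations

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

# Each entry: property name -> 20 values in AA_ORDER.
_SCALES: dict[str, list[float]] = {
    # Kyte & Doolittle hydropathy
    "hydropathy_kd": [1.8, -4.5, -3.5, -3.5, 2.5, -3.5, -3.5, -0.4, -3.2,
                      4.5, 3.8, -3.9, 1.9, 2.8, -1.6, -0.8, -0.7, -0.9, -1.3, 4.2],
    # Eisenberg consensus hydrophobicity
    "hydrophobicity_eisenberg": [0.62, -2.53, -0.78, -0.90, 0.29, -0.85, -0.74, 0.48, -0.40,
                                 1.38, 1.06, -1.50, 0.64, 1.19, 0.12, -0.18, -0.05, 0.81, 0.26, 1.08],
    # Fauchere & Pliska octanol/water transfer
    "hydrophobicity_fp": [0.31, -1.01, -0.60, -0.77, 1.54, -0.22, -0.64, 0.00, 0.13,
                          1.80, 1.70, -0.99, 1.23, 1.79, 0.72, -0.04, 0.26, 2.25, 0.96, 1.22],
    # Hopp & Woods hydrophilicity
    "hydrophilicity_hw": [-0.5, 3.0, 0.2, 3.0, -1.0, 0.2, 3.0, 0.0, -0.5,
                          -1.8, -1.8, 3.0, -1.3, -2.5, 0.0, 0.3, -0.4, -3.4, -2.3, -1.5],
    # Wimley & White membrane-interface transfer free energy (kcal/mol)
    "interface_ww": [0.17, 0.81, 0.42, 1.23, -0.24, 0.58, 2.02, 0.01, 0.17,
                     -0.31, -0.56, 0.99, -0.23, -1.13, 0.45, 0.13, 0.14, -1.85, -0.94, 0.07],
    # Grantham polarity
    "polarity_grantham": [8.1, 10.5, 11.6, 13.0, 5.5, 10.5, 12.3, 9.0, 10.4,
                          5.2, 4.9, 11.3, 5.7, 5.2, 8.0, 9.2, 8.6, 5.4, 6.2, 5.9],
    # free amino-acid molecular weight (Da)
    "molecular_weight": [89.09, 174.20, 132.12, 133.10, 121.16, 146.15, 147.13, 75.07, 155.16,
                         131.17, 131.17, 146.19, 149.21, 165.19, 115.13, 105.09, 119.12,
                         204.23, 181.19, 117.15],
    # formal side-chain charge near pH 7 (His given a small positive fraction)
    "net_charge_ph7": [0, 1, 0, -1, 0, 0, -1, 0, 0.1,
                       0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0],
    "isoelectric_point": [6.00, 10.76, 5.41, 2.77, 5.07, 5.65, 3.22, 5.97, 7.59,
                          6.02, 5.98, 9.74, 5.74, 5.48, 6.30, 5.68, 5.60, 5.89, 5.66, 5.96],
    # Zamyatnin residue volume (A^3)
    "volume_a3": [88.6, 173.4, 114.1, 111.1, 108.5, 143.8, 138.4, 60.1, 153.2,
                  166.7, 166.7, 168.6, 162.9, 189.9, 112.7, 89.0, 116.1, 227.8, 193.6, 140.0],
    # Tien et al. theoretical maximum accessible surface area (A^2)
    "max_asa_a2": [129, 274, 195, 193, 167, 225, 223, 104, 224,
                   197, 201, 236, 224, 240, 159, 155, 172, 285, 263, 174],
    # Chou & Fasman conformational propensities
    "helix_propensity_cf": [1.42, 0.98, 0.67, 1.01, 0.70, 1.11, 1.51, 0.57, 1.00,
                            1.08, 1.21, 1.16, 1.45, 1.13, 0.57, 0.77, 0.83, 1.08, 0.69, 1.06],
    "sheet_propensity_cf": [0.83, 0.93, 0.89, 0.54, 1.19, 1.10, 0.37, 0.75, 0.87,
                            1.60, 1.30, 0.74, 1.05, 1.38, 0.55, 0.75, 1.19, 1.37, 1.47, 1.70],
    "turn_propensity_cf": [0.66, 0.95, 1.56, 1.46, 1.19, 0.98, 0.74, 1.56, 0.95,
                           0.47, 0.59, 1.01, 0.60, 0.60, 1.52, 1.43, 0.96, 0.96, 1.14, 0.50],
    # atom composition (heavy atoms; backbone contributes 4)
    "heavy_atoms": [5, 11, 8, 8, 6, 9, 9, 4, 10, 8, 8, 9, 8, 11, 7, 6, 7, 14, 12, 7],
    "sidechain_carbons": [1, 4, 2, 2, 1, 3, 3, 0, 4, 4, 4, 4, 3, 7, 3, 1, 2, 9, 7, 3],
    "sidechain_nitrogens": [0, 3, 1, 0, 0, 1, 0, 0, 2, 0, 0, 1, 0, 0, 0, 0, 0, 1, 0, 0],
    "sidechain_oxygens": [0, 0, 1, 2, 0, 1, 2, 0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 0, 1, 0],
    "sidechain_sulfurs": [0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0],
    # side-chain hydrogen-bonding group counts (package convention)
    "hbond_donors_sc": [0, 4, 1, 0, 1, 1, 0, 0, 1, 0, 0, 1, 0, 0, 0, 1, 1, 1, 1, 0],
    "hbond_acceptors_sc": [0, 0, 1, 2, 0, 1, 2, 0, 1, 0, 0, 0, 0, 0, 0, 1, 1, 0, 1, 0],
    # number of side-chain chi torsions
    "rotatable_bonds_sc": [0, 4, 2, 2, 1, 3, 3, 0, 2, 2, 2, 4, 3, 2, 0, 1, 1, 2, 2, 1],
    # chemical-class indicators
    "is_aromatic": [0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1, 0, 0, 0, 1, 1, 0],
    "is_aliphatic": [1, 0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 1],
    "is_polar_uncharged": [0, 0, 1, 0, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 0, 1, 0],
    "is_positively_ionizable": [0, 1, 0, 0, 0, 0, 0, 0, 1, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0],
    "is_negatively_ionizable": [0, 0, 0, 1, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    # residue volume <= 120 A^3
    "is_small": [1, 0, 1, 1, 1, 0, 0, 1, 0, 0, 0, 0, 0, 0, 1, 1, 1, 0, 0, 0],
}


def default_scales() -> dict[str, list[float]]:
    """Return the 48-property default set: 28 scales + 20 identity indicators."""
    scales = dict(_SCALES)
    for j, aa in enumerate(AA_ORDER):
        scales[f"identity_{aa}"] = [1.0 if i == j else 0.0 for i in range(20)]
    return scales
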