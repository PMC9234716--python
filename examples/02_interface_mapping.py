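"""Map candidate residues onto a trimer and find inter-subunit pockets.

Builds a C3-symmetric toy trimer (560 residues per chain) with six planted
interface residues — the numbering mirrors the determinants of a
peptide-gated channel study (231, 281, 288, 316, 447, 529) — then flags
candidates lying within 8 Å (Cα) of an adjacent subunit and clusters them
into pockets. All six planted residues land in one pocket.
"""

from peptidegate import detect_interface_residues, simulate_trimer

PLANTED = (231, 281, 288, 316, 447, 529)

structure, truth = simulate_trimer(560, PLANTED, interface_radius=5.0, seed=7)
report = detect_interface_residues(structure, list(range(1, 561)))

print(f"cutoff: {report.cutoff} Å ({report.atom_mode} atoms)")
print(f"interfacial residues: {report.flagged_res_ids}")
for hit in report.interfacial[:6]:
    print(f"  chain {hit.chain} residue {hit.res_id}: "
          f"{hit.distance:.2f} Å to chain {hit.partner_chain}")
for p in report.pockets:
    print(f"pocket: residues {p['residues']} "
          f"(linkage diameter {p['diameter']:.1f} Å)")
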