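"""Physicochemical characterization and the published family reference.

Profiles one sequence (length, MW, pI, GRAVY, instability, aliphatic
index) and then summarizes the bundled 28-member kiwifruit XYLP property
table the same way a family-wide report would.
"""

from xylpscan.core_io import ProteinRecord
from xylpscan.datasets import load_reference_properties
from xylpscan.physchem import physchem_profile

protein = ProteinRecord(
    "demo", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQ")
p = physchem_profile(protein)
print(f"{p.protein_id}: {p.length} aa, {p.mw:.2f} kDa, pI {p.pi:.2f}, "
      f"GRAVY {p.gravy:.3f}, instability {p.instability:.2f}, "
      f"aliphatic {p.aliphatic:.2f}")
print(f"  alkaline={p.is_alkaline} unstable={p.is_unstable} "
      f"hydrophobic={p.is_hydrophobic}")

df = load_reference_properties()
print(f"\nkiwifruit XYLP family reference ({len(df)} members):")
print(f"  alkaline (pI > 7): {int((df['pi'] > 7).sum())}")
print(f"  pI range: {df['pi'].min():.2f} - {df['pi'].max():.2f}")
print(f"  length range: {int(df['length'].min())} - {int(df['length'].max())} aa")
print(f"  stable (instability < 40): "
      f"{', '.join(df.loc[df['instability_index'] < 40, 'gene_name'])}")
print(f"  hydrophilic (GRAVY < 0): "
      f"{', '.join(df.loc[df['gravy'] < 0, 'gene_name'])}")
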