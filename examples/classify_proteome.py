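"""Classify a proteome with the three-part XYLP membership rule.

Builds a small synthetic proteome with planted family members and decoys,
applies the classifier, and prints the verdict tally plus the evidence for
one accepted protein.  With perfect recovery the accepted set equals the
planted set.
"""

from xylpscan.synthetic_data import gen_xylp_proteome
from xylpscan.xylp_classify import classify_xylp, name_candidates

records, truth = gen_xylp_proteome(seed=1)
calls = [classify_xylp(rec) for rec in records]
names = name_candidates(calls, prefix="XYLP")

accepted = [c for c in calls if c.verdict == "XYLP"]
print(f"proteins screened : {len(calls)}")
print(f"accepted as XYLP  : {len(accepted)} (planted: {len(truth.xylp_ids)})")
print(f"recovered planted : {sorted(c.protein_id for c in accepted) == sorted(truth.xylp_ids)}")

call = accepted[0]
region = call.past_regions[0]
print(f"\nexample: {call.protein_id} -> {names[call.protein_id]}")
print(f"  PAST region {region.start}-{region.end} "
      f"({region.past_fraction:.0%} PAST)")
print(f"  glycomodules in region: {len(call.glyco_hits)}")
print(f"  nsLTP cysteines at: {call.motif.cys_positions}")
print(f"  residue between C5/C6: {call.motif.inter56_residue} "
      f"(hydrophobic: {call.motif.inter56_hydrophobic})")
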