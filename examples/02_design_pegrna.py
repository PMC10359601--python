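"""Assemble a pegRNA for a +5 G-to-T substitution on a toy locus.

Shows the component derivation: PBS complementary to the last L nt of the
nicked strand, RTT templating the edited strand from the nick outward.
"""

from pegtherm import EditSpec, assemble, nick_position
from pegtherm.synthetic import make_toy_locus

locus = make_toy_locus(gc_frac=0.5, seed=11)
print(f"protospacer: {locus.protospacer}  PAM: {locus.pam}")
print(f"nick after protospacer position 17 (window offset {nick_position(locus)})")

down = locus.downstream_of_nick()
edit = EditSpec("substitution", 5, ref=down[4], alt="T" if down[4] != "T" else "A")
print(f"edit: +5 {edit.ref}>{edit.alt} (position +1 = first nt 3' of the nick)")

peg = assemble(locus, edit, pbs_len=7, ha_len=10, name="toy+5")
print(f"\npegRNA ({len(peg)} nt, 5'->3'):")
for part, (start, end) in peg.boundaries.items():
    print(f"  {part:9s} [{start:3d},{end:3d})  {getattr(peg, part) or ''}")
# The RTT 3' terminus abuts the PBS and templates position +1 first, so the
# reverse transcriptase copies the edit immediately after priming.
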