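"""Inspect the conserved structure of a trained LTR profile.

Trains a model on a synthetic family, then extracts its consensus, the
per-column information content (2 bits = fully conserved), the degenerate
IUPAC consensus, the conserved-motif positions, and the short-inverted-
repeat (SIR) report checking that the two LTR termini are complementary.
"""

from ltrhmm import (
    LTRFamilySpec, consensus_from_model, iupac_consensus, logo_matrix,
    make_family, motif_report, sir_report, train_with_noise,
)

seqs, truth = make_family(LTRFamilySpec(n_sequences=25, core_length=100, seed=3))
model, _ = train_with_noise(seqs, M=100, z=0.05, seed=3, max_iter=20, tol=1e-2)

cons = consensus_from_model(model).residues
print("consensus :", cons)
print("degenerate:", iupac_consensus(model))

logo = logo_matrix(model)
print(f"mean information content {logo.bits.mean():.2f} bits/column; "
      f"{int((logo.bits > 1.5).sum())} columns above 1.5 bits")

for name, hits in motif_report(cons).items():
    if hits:
        print(f"motif {name:<11} at", [h["start"] for h in hits])

sir = sir_report(model, window=7)
print(f"SIRs: 5' {sir.five_prime} / 3' {sir.three_prime} "
      f"-> complementarity {sir.complementarity:.2f}")
# complementarity 1.0 means every terminal position of the 3' SIR is
# compatible with the reverse complement of the 5' SIR, as planted.
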