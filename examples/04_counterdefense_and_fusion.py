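"""Remote counter-defense homologs and fusion detection.

First screens a candidate that shares only its fold (not its sequence)
with a known counter-defense protein: retained when TM > 0.6, the shorter
chain is ≥ 70% of the longer, and the sequences are divergent. Then builds
a candidate by concatenating two different reference folds and shows the
fusion scan flag it: two reference hits whose aligned segments barely
overlap (Jaccard < 0.25).
"""

import numpy as np

from phagescan import screens
from phagescan import synthetic_data as sd
from phagescan.io_formats import ProteinRecord, StructureModel
from phagescan.screens import CandidateReport, ReferenceHit
from phagescan.structalign import structure_align

rng = np.random.default_rng(0)

# --- remote homolog of a counter-defense reference
ref_seq = sd._random_residues(200, rng)
ref = ProteinRecord("anti_restriction_ref", ref_seq)
ref_fold = sd.gen_fold("helix_hairpin", 200, seed=1)
ref_structs = {ref.protein_id: StructureModel(ref.protein_id,
                                              ref_fold.coords, ref_seq)}
cand_seq = sd._plant_sequence(ref_seq, 180, rng, [ref])
cand_fold = sd.perturb_structure(ref_structs[ref.protein_id], 0.6, True, 2)
cand = ProteinRecord("phage_candidate", cand_seq)
pairs = screens.counterdefense_screen(
    [cand], {"phage_candidate": StructureModel(
        "phage_candidate", cand_fold.coords[:180], cand_seq)},
    [ref], ref_structs)
p = pairs[0]
print(f"counter-defense pair: TM={p.tm_shorter:.3f} "
      f"len_ratio={p.len_ratio:.2f} identity={p.identity:.2f} "
      f"-> retained={p.retained}")

# --- fusion of two reference folds
f1 = sd.gen_fold("helix_hairpin", 60, seed=3)
f2 = sd.gen_fold("strand", 50, seed=4)
refA = StructureModel("acrA", f1.coords, f1.residues)
refB = StructureModel("acrB", f2.coords, f2.residues)
shift = f1.coords[-1] + np.array([10.0, 0, 0])
fused = StructureModel("fused_candidate",
                       np.vstack([f1.coords, f2.coords - f2.coords[0] + shift]),
                       f1.residues + f2.residues)
fused = sd.perturb_structure(fused, 0.5, True, seed=5)

rep = CandidateReport("fused_candidate")
for r in (refA, refB):
    aln = structure_align(fused, r)
    rep.reference_hits.append(ReferenceHit(
        r.protein_id, aln.tm_query, aln.tm_target, aln.tm_shorter,
        aln.rmsd, 0.0, 99.0,
        query_indices=frozenset(i for i, _ in aln.pairs)))
    print(f"fused candidate vs {r.protein_id}: TM={aln.tm_shorter:.3f}")

for f in screens.fusion_scan([rep]):
    print(f"fusion scan: refs={f.reference_ids} "
          f"segments={f.intervals} jaccard={f.jaccard:.3f} "
          f"putative_fusion={f.putative_fusion}")
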