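"""Simulate the MEKi time-course study with known ground truth.

Generates RNA counts plus protein/phosphopeptide log-abundances driven by
four latent "waves" of MAPK pathway activity, and the companion
prior-knowledge tables.  Prints what was planted so downstream examples can
be judged against it.
"""

from oiswaves.synthetic import (KnowledgeParams, TimeCourseDesign,
                                generate_knowledge_bases, generate_timecourse)

design = TimeCourseDesign(seed=1)
ds = generate_timecourse(design)

print("views (features x samples):")
for name, mat in ds.views.items():
    miss = float(mat.isna().to_numpy().mean())
    print(f"  {name:8s} {mat.shape}  missing fraction {miss:.2f}")

print("\nwave time (minutes) per planted factor:", ds.truth["wave_time"])
print("planted OIS_UP genes (up in senescence, down upon MEKi):",
      len(ds.truth["ois_up_genes"]))
print("planted OIS_DN genes:", len(ds.truth["ois_dn_genes"]))

kb = generate_knowledge_bases(ds.truth, KnowledgeParams(seed=1))
print(f"\nknowledge tables: {len(kb.senescence_evidence)} senescence-evidence"
      f" genes, {len(kb.ppi)} PPI edges, {len(kb.interactions)} signed"
      f" interactions, {kb.kinase_substrate.kinase.nunique()} kinases,"
      f" {kb.tf_target.tf.nunique()} TFs")
# The planted signature genes carry >= 3 concordant senescence publications
# and form a dense PPI module against a sparse background - exactly the
# structure the network stage is expected to detect.
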