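"""Run the full structure pipeline on a toy crystal scene.

Builds a P1 cell holding a pseudo-peptide, 30 planted waters and 2 planted
sulfates; synthesizes 2Fo-Fc and solvent-omit Fo-Fc maps; then picks
difference peaks, extracts the 21 features at each, scores, classifies
under three priors, runs triage (clustering, model-error and split-peak
checks) and emits a solvent-only model.  Takes a couple of minutes: the
classifier is first trained on features extracted from a batch of smaller
scenes.
"""

from solventscope import run_pipeline, write_structure
from solventscope.synthetic import SceneConfig, make_scene, scene_reference_model

print("training the scene-feature classifier (a few minutes)...")
model = scene_reference_model(seed=0)

cfg = SceneConfig(n_waters=30, n_sulfates=2, cell_edge=40.0, seed=11)
structure, two_fofc, fofc, truth = make_scene(cfg)

report, assignments, solvent = run_pipeline(structure, two_fofc, fofc, model,
                                            verbose=True)
print(f"\n{len(report)} peaks evaluated")
print(report.predicted_class.value_counts().to_string())
print(f"{len(assignments)} solvent models emitted "
      f"({sum(a.cls == 'sulfate' for a in assignments)} sulfate)")
write_structure(solvent, "/tmp/solventscope_solvent.pdb")
print("solvent model written to /tmp/solventscope_solvent.pdb")
# each sulfate site should appear as a 'representative' with its four
# oxygen-position peaks absorbed as part_of_representative_model
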