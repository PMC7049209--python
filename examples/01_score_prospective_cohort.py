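"""Score the packaged prospective cohort and rank each patient's aneurysms.

34 SAH patients with multiple intracranial aneurysms; for each patient the
aneurysm with the maximal score is the predicted bleeding source.
"""

from mia_score import published_coefficients, score_accuracy, score_frame, table2_fixture

cohort = table2_fixture()
coeffs = published_coefficients()

frame = score_frame(cohort, coeffs)
print(frame[["patient_id", "aneurysm_id", "size_mm", "location", "shape",
             "score_rounded", "is_argmax"]].head(9).to_string(index=False))

acc = score_accuracy(cohort, coeffs, tie_policy="non_strict")
print(f"\nbleeding source attains the maximal score in "
      f"{int(acc.hit.sum())}/{len(acc)} patients")
print("missed:", acc.loc[~acc.hit, "patient_id"].tolist(),
      "(surgical finding contradicts the printed score ordering there)")
# A higher score means higher rupture risk; is_argmax marks the predicted
# bleeding source within each patient.
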