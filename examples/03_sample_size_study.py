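"""How training-set size affects the BePhyEn model.

Cross-validated training accuracy and macro one-vs-rest AUC both rise
with n and begin to saturate around a few hundred samples — the reason
120 samples is a reasonable operating point for this model family.
"""

from bpsdmon import sample_size_study

table = sample_size_study("bephyen", sizes=(60, 120, 240, 480), seeds=range(5))
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\ncv_accuracy: 5-fold cross-validated accuracy on the training set;")
print("cv_auc: macro one-vs-rest AUC from leaf class frequencies.")
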