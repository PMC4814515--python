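study_id,n_patients,n_controls,acc_cv,acc_test,cohort_tag
kawasaki_train_test,30,30,77,84,other
iwabuchi_3T,,,67,,chronic-mixed
iwabuchi_7T,,,77,,chronic-mixed
nieuwenhuis_top10,,,86.8,69.1,chronic-mixed
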