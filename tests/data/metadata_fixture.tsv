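sample_id	age	sex	bmi	country	body_site	body_subsite	ibd	diabetes	antibiotics_past_month	pregnant	hospitalized	disabled	critically_ill
v_age	17.9	female	24.0	US	gut	feces	False	False	False	False	False	False	False
v_bmi	45.0	male	31.5	US	gut	feces	False	False	False	False	False	False	False
v_ibd	45.0	female	24.0	US	gut	feces	True	False	False	False	False	False	False
v_diabetes	45.0	male	24.0	US	gut	feces	False	True	False	False	False	False	False
v_antibiotics	45.0	female	24.0	US	gut	feces	False	False	True	False	False	False	False
v_pregnant	45.0	female	24.0	US	gut	feces	False	False	False	True	False	False	False
v_hospitalized	45.0	male	24.0	US	gut	feces	False	False	False	False	True	False	False
v_disabled	45.0	female	24.0	US	gut	feces	False	False	False	False	False	True	False
v_critically_ill	45.0	male	24.0	US	gut	feces	False	False	False	False	False	False	True
v_missing		female	24.0	US	gut	feces	False	False	False	False	False	False	False
clean_boundary_low	18.0	female	18.5	US	gut	feces	False	False	False	False	False	False	False
clean_boundary_high	90.0	male	30.0	US	gut	feces	False	False	False	False	False	False	False
clean_mid	45.0	female	24.0	US	gut	feces	False	False	False	False	False	False	False
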