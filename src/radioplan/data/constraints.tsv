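# Clinical dose-volume constraints and target coverage requirements.
# constraint_set: physical_20fx (doses on the 20-fraction physical scale)
#                 or eqd2 (doses on the EQD2 scale).
# kind: V_at_dose (volume receiving >= dose_gy, compared le limit),
#       D_at_volume (dose covering volume_pct of the structure),
#       D_max (maximum dose).
# unit of the limit: pct, cm3 or Gy.
# The eqd2 rectum rows are encoded verbatim from the source protocol table.
constraint_set	structure	kind	dose_gy	volume_pct	op	limit	unit
physical_20fx	ptv2	D_at_volume		98	ge	58.8	Gy
physical_20fx	ptv2	D_at_volume		2	le	70	Gy
physical_20fx	ptv3	D_at_volume		98	ge	68.6	Gy
physical_20fx	ptv3	D_at_volume		2	le	71.4	Gy
physical_20fx	rectum	V_at_dose	20		le	85	pct
physical_20fx	rectum	V_at_dose	30		le	57	pct
physical_20fx	rectum	V_at_dose	40		le	50	pct
physical_20fx	rectum	V_at_dose	50		le	35	pct
physical_20fx	rectum	V_at_dose	60		le	3	pct
physical_20fx	bladder	V_at_dose	40		le	50	pct
physical_20fx	bladder	V_at_dose	50		le	35	pct
physical_20fx	bladder	V_at_dose	60		le	5	pct
physical_20fx	bladder	V_at_dose	67		le	1	cm3
physical_20fx	femoral_head_left	V_at_dose	41		le	50	pct
physical_20fx	femoral_head_right	V_at_dose	41		le	50	pct
physical_20fx	small_bowel	V_at_dose	41		le	17	cm3
physical_20fx	small_bowel	D_max			le	47	Gy
physical_20fx	sigmoid_colon	V_at_dose	53		le	3	cm3
physical_20fx	penile_bulb	V_at_dose	41		le	50	pct
physical_20fx	penile_bulb	V_at_dose	49		le	20	pct
eqd2	ptv2	D_at_volume		98	ge	74.2	Gy
eqd2	ptv2	D_at_volume		2	le	99.2	Gy
eqd2	ptv3	D_at_volume		98	ge	95.9	Gy
eqd2	ptv3	D_at_volume		2	le	102.5	Gy
eqd2	rectum	V_at_dose	26		le	65.4	pct
eqd2	rectum	V_at_dose	30		le	49.5	pct
eqd2	rectum	V_at_dose	40		le	38.6	pct
eqd2	rectum	V_at_dose	50		le	31.5	pct
eqd2	rectum	V_at_dose	60		le	17.5	pct
eqd2	rectum	V_at_dose	70		le	2.3	pct
eqd2	bladder	V_at_dose	40		le	50	pct
eqd2	bladder	V_at_dose	55		le	35	pct
eqd2	bladder	V_at_dose	72		le	5	pct
eqd2	bladder	V_at_dose	85.1		le	1	cm3
eqd2	femoral_head_left	V_at_dose	41.4		le	50	pct
eqd2	femoral_head_right	V_at_dose	41.4		le	50	pct
eqd2	small_bowel	V_at_dose	41.4		le	17	cm3
eqd2	small_bowel	D_max			le	50.3	Gy
eqd2	sigmoid_colon	V_at_dose	59.9		le	3	cm3
eqd2	penile_bulb	V_at_dose	41.4		le	50	pct
eqd2	penile_bulb	V_at_dose	53.41		le	20	pct
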