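SC-F1	synthetic placeholder markers for subset SC-F1	SYNMARK_SCF1_1	SYNMARK_SCF1_2	SYNMARK_SCF1_3	SYNMARK_SCF1_4	SYNMARK_SCF1_5
SC-F2	synthetic placeholder markers for subset SC-F2	SYNMARK_SCF2_1	SYNMARK_SCF2_2	SYNMARK_SCF2_3	SYNMARK_SCF2_4	SYNMARK_SCF2_5
SC-F3	synthetic placeholder markers for subset SC-F3	SYNMARK_SCF3_1	SYNMARK_SCF3_2	SYNMARK_SCF3_3	SYNMARK_SCF3_4	SYNMARK_SCF3_5
SC-F4	synthetic placeholder markers for subset SC-F4	SYNMARK_SCF4_1	SYNMARK_SCF4_2	SYNMARK_SCF4_3	SYNMARK_SCF4_4	SYNMARK_SCF4_5
SC-M1	synthetic placeholder markers for subset SC-M1	SYNMARK_SCM1_1	SYNMARK_SCM1_2	SYNMARK_SCM1_3	SYNMARK_SCM1_4	SYNMARK_SCM1_5
SC-M2	synthetic placeholder markers for subset SC-M2	SYNMARK_SCM2_1	SYNMARK_SCM2_2	SYNMARK_SCM2_3	SYNMARK_SCM2_4	SYNMARK_SCM2_5
SC-M3	synthetic placeholder markers for subset SC-M3	SYNMARK_SCM3_1	SYNMARK_SCM3_2	SYNMARK_SCM3_3	SYNMARK_SCM3_4	SYNMARK_SCM3_5
SC-M4	synthetic placeholder markers for subset SC-M4	SYNMARK_SCM4_1	SYNMARK_SCM4_2	SYNMARK_SCM4_3	SYNMARK_SCM4_4	SYNMARK_SCM4_5
SC-T1	synthetic placeholder markers for subset SC-T1	SYNMARK_SCT1_1	SYNMARK_SCT1_2	SYNMARK_SCT1_3	SYNMARK_SCT1_4	SYNMARK_SCT1_5
SC-T2	synthetic placeholder markers for subset SC-T2	SYNMARK_SCT2_1	SYNMARK_SCT2_2	SYNMARK_SCT2_3	SYNMARK_SCT2_4	SYNMARK_SCT2_5
SC-T3	synthetic placeholder markers for subset SC-T3	SYNMARK_SCT3_1	SYNMARK_SCT3_2	SYNMARK_SCT3_3	SYNMARK_SCT3_4	SYNMARK_SCT3_5
SC-T4	synthetic placeholder markers for subset SC-T4	SYNMARK_SCT4_1	SYNMARK_SCT4_2	SYNMARK_SCT4_3	SYNMARK_SCT4_4	SYNMARK_SCT4_5
SC-T5	synthetic placeholder markers for subset SC-T5	SYNMARK_SCT5_1	SYNMARK_SCT5_2	SYNMARK_SCT5_3	SYNMARK_SCT5_4	SYNMARK_SCT5_5
SC-T6	synthetic placeholder markers for subset SC-T6	SYNMARK_SCT6_1	SYNMARK_SCT6_2	SYNMARK_SCT6_3	SYNMARK_SCT6_4	SYNMARK_SCT6_5
SC-B1	synthetic placeholder markers for subset SC-B1	SYNMARK_SCB1_1	SYNMARK_SCB1_2	SYNMARK_SCB1_3	SYNMARK_SCB1_4	SYNMARK_SCB1_5
SC-B2	synthetic placeholder markers for subset SC-B2	SYNMARK_SCB2_1	SYNMARK_SCB2_2	SYNMARK_SCB2_3	SYNMARK_SCB2_4	SYNMARK_SCB2_5
SC-B3	synthetic placeholder markers for subset SC-B3	SYNMARK_SCB3_1	SYNMARK_SCB3_2	SYNMARK_SCB3_3	SYNMARK_SCB3_4	SYNMARK_SCB3_5
SC-B4	synthetic placeholder markers for subset SC-B4	SYNMARK_SCB4_1	SYNMARK_SCB4_2	SYNMARK_SCB4_3	SYNMARK_SCB4_4	SYNMARK_SCB4_5
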