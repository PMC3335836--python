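item,centre,price_usd_2008,scenario_set
first_line_zdv3tc_tdf,all,349.12,observed
first_line_zdv3tc_nvp,all,308.79,observed
first_line_zdv3tc_abc,all,585.46,observed
second_line_ddi_efv_kal,all,1032.59,observed
second_line_ddi_nvp_kal,all,967.98,observed
second_line_ddi_abc_kal,all,1244.65,observed
cd4_test,Entebbe,15.79,observed
cd4_test,Kampala,10.07,observed
cd4_test,Harare,18.82,observed
haematology_panel,Entebbe,6.46,observed
haematology_panel,Kampala,7.13,observed
haematology_panel,Harare,12.32,observed
biochemistry_panel,Entebbe,11.66,observed
biochemistry_panel,Kampala,10.67,observed
biochemistry_panel,Harare,12.23,observed
clinic_visit,Entebbe,4.08,observed
clinic_visit,Kampala,3.30,observed
clinic_visit,Harare,8.38,observed
health_centre_visit,Entebbe,3.26,observed
health_centre_visit,Kampala,8.84,observed
health_centre_visit,Harare,8.73,observed
hospital_per_diem,all,25.57,observed
other_diagnostic,all,6.26,observed
concomitant_flat_lcm,all,46.0,observed
concomitant_flat_cdm,all,48.0,observed
first_line_zdv3tc_tdf,all,290.72,generic_first_line
first_line_zdv3tc_nvp,all,165.64,generic_first_line
first_line_zdv3tc_abc,all,441.80,generic_first_line
second_line_ddi_efv_kal,all,874.18,lower_bound_second_line
second_line_ddi_nvp_kal,all,763.22,lower_bound_second_line
second_line_ddi_abc_kal,all,1062.52,lower_bound_second_line
cd4_test,all,8.82,national_referral_lab
haematology_panel,all,5.30,national_referral_lab
biochemistry_panel,all,29.50,national_referral_lab
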