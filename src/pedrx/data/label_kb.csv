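atc_code,compound_name,compound_class,min_age_years,indication_prefixes,source_year,device_or_product_note
R03AC02,Salbutamol (inhaled),inhaled_saba,0,J43;J44;J45;J46,2004,
R03AC02,Salbutamol (inhaled),inhaled_saba,0,J43;J44;J45;J46,2008,
R03AC04,Fenoterol,inhaled_saba,4,J43;J44;J45;J46,2004,
R03AC04,Fenoterol,inhaled_saba,4,J43;J44;J45;J46,2008,
R03AC03,Terbutaline (inhaled),inhaled_saba,5,J43;J44;J45;J46,2004,
R03AC03,Terbutaline (inhaled),inhaled_saba,5,J43;J44;J45;J46,2008,
R03AK03,Ipratropium/Fenoterol,inhaled_saba_combination,0,J44;J45;J46,2004,fixed combination
R03AK03,Ipratropium/Fenoterol,inhaled_saba_combination,0,J44;J45;J46,2008,fixed combination
R03AK05,Reproterol/Cromoglicic acid,inhaled_saba_combination,0,J45;J46,2004,fixed combination
R03AK05,Reproterol/Cromoglicic acid,inhaled_saba_combination,0,J45;J46,2008,fixed combination
R03AC12,Salmeterol,inhaled_laba,4,J44;J45;J46,2004,
R03AC12,Salmeterol,inhaled_laba,4,J44;J45;J46,2008,
R03AC13,Formoterol,inhaled_laba,6,J44;J45;J46,2004,
R03AC13,Formoterol,inhaled_laba,6,J44;J45;J46,2008,
R03AK06,Salmeterol/Fluticasone,inhaled_laba_ics,4,J44;J45;J46,2004,fixed combination
R03AK06,Salmeterol/Fluticasone,inhaled_laba_ics,4,J44;J45;J46,2008,fixed combination
R03AK27,Formoterol/Beclomethasone,inhaled_laba_ics,6,J45;J46,2004,fixed combination
R03AK27,Formoterol/Beclomethasone,inhaled_laba_ics,6,J45;J46,2008,fixed combination
R03AK28,Formoterol/Budesonide,inhaled_laba_ics,6,J44;J45;J46,2004,fixed combination
R03AK28,Formoterol/Budesonide,inhaled_laba_ics,6,J44;J45;J46,2008,fixed combination
R03BB01,Ipratropium,sama,0,J44;J45;J46,2004,
R03BB01,Ipratropium,sama,0,J44;J45;J46,2008,
R03BB04,Tiotropium,lama,18,J44,2004,
R03BB04,Tiotropium,lama,18,J44,2008,
R03BA02,Budesonide,ics,0,J41;J42;J43;J44;J45;J46,2004,
R03BA02,Budesonide,ics,0,J41;J42;J43;J44;J45;J46,2008,
R03BA01,Beclomethasone,ics,0,J41;J42;J43;J44;J45;J46,2004,
R03BA01,Beclomethasone,ics,0,J41;J42;J43;J44;J45;J46,2008,
R03BA05,Fluticasone,ics,4,J44;J45;J46,2004,
R03BA05,Fluticasone,ics,4,J44;J45;J46,2008,
R03BA08,Ciclesonide,ics,12,J45;J46,2004,
R03BA08,Ciclesonide,ics,12,J45;J46,2008,
R03CC02,Salbutamol (oral),oral_b2a,0,J43;J44;J45;J46,2004,
R03CC02,Salbutamol (oral),oral_b2a,0,J43;J44;J45;J46,2008,
R03CC03,Terbutaline (oral),oral_b2a,0,J43;J44;J45;J46,2004,
R03CC03,Terbutaline (oral),oral_b2a,0,J43;J44;J45;J46,2008,
R03CC11,Tulobuterol,oral_b2a,1,J43;J44;J45;J46,2004,
R03CC11,Tulobuterol,oral_b2a,1,J43;J44;J45;J46,2008,
R03CC13,Clenbuterol,oral_b2a,0,J41;J42;J43;J45;J46,2004,
R03CC13,Clenbuterol,oral_b2a,0,J41;J42;J43;J45;J46,2008,
R03CC63,Clenbuterol/Ambroxol,oral_b2a_combination,0,J20;J41;J42;J43;J45;J46,2004,fixed combination
R03CC63,Clenbuterol/Ambroxol,oral_b2a_combination,0,J20;J41;J42;J43;J45;J46,2008,fixed combination
R03DA04,Theophylline,other,1,J44;J45;J46,2004,
R03DA04,Theophylline,other,1,J44;J45;J46,2008,
R03DC03,Montelukast,other,1,J45;J46,2004,
R03DC03,Montelukast,other,1,J45;J46,2008,
R03BC01,Cromoglicic acid,other,2,J45;J46,2004,
R03BC01,Cromoglicic acid,other,2,J45;J46,2008,
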