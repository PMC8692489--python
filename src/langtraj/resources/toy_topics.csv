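topic_id,term,weight
t_rescue,rubble,0.9
t_rescue,debris,0.9
t_rescue,smoke,0.9
t_rescue,site,0.9
t_rescue,dust,0.6
t_health,dust,0.4
t_health,doctor,0.9
t_health,breathing,0.9
t_health,cough,0.9
t_health,clinic,0.9
t_distress,worried,0.9
t_distress,nervous,0.9
t_distress,afraid,0.9
t_distress,sad,0.9
t_distress,hopeless,0.9
t_family,family,0.9
t_family,wife,0.9
t_family,kids,0.9
t_family,home,0.9
t_family,brother,0.9
t_work,shift,0.9
t_work,duty,0.9
t_work,truck,0.9
t_work,gear,0.9
t_work,radio,0.9
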