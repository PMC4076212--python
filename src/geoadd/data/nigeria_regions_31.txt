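31
Yobe 3 Bauchi/Gombe Borno Jigawa
Abia 6 Akwa_Ibom Anambra Cross_River Enugu/Ebonyi Imo Rivers/Bayelsa
Abuja 4 Kaduna Kogi Nassarawa/Plateau Niger
Adamawa 3 Bauchi/Gombe Borno Taraba
Akwa_Ibom 3 Abia Cross_River Rivers/Bayelsa
Anambra 5 Abia Delta Enugu/Ebonyi Imo Kogi
Bauchi/Gombe 8 Adamawa Borno Jigawa Kaduna Kano Nassarawa/Plateau Taraba Yobe
Benue 5 Cross_River Enugu/Ebonyi Kogi Nassarawa/Plateau Taraba
Borno 3 Adamawa Bauchi/Gombe Yobe
Cross_River 4 Abia Akwa_Ibom Benue Enugu/Ebonyi
Delta 4 Anambra Edo Ondo/Ekiti Rivers/Bayelsa
Edo 3 Delta Kogi Ondo/Ekiti
Enugu/Ebonyi 5 Abia Anambra Benue Cross_River Kogi
Imo 3 Abia Anambra Rivers/Bayelsa
Jigawa 4 Bauchi/Gombe Kano Katsina Yobe
Kaduna 7 Abuja Bauchi/Gombe Kano Katsina Nassarawa/Plateau Niger Sokoto/Zamfara
Kano 4 Bauchi/Gombe Jigawa Kaduna Katsina
Katsina 4 Jigawa Kaduna Kano Sokoto/Zamfara
Kebbi 2 Niger Sokoto/Zamfara
Kogi 9 Abuja Anambra Benue Edo Enugu/Ebonyi Kwara Nassarawa/Plateau Niger Ondo/Ekiti
Kwara 5 Kogi Niger Ondo/Ekiti Osun Oyo
Lagos 1 Ogun
Nassarawa/Plateau 6 Abuja Bauchi/Gombe Benue Kaduna Kogi Taraba
Niger 6 Abuja Kaduna Kebbi Kogi Kwara Sokoto/Zamfara
Ogun 4 Lagos Ondo/Ekiti Osun Oyo
Ondo/Ekiti 6 Delta Edo Kogi Kwara Ogun Osun
Osun 4 Kwara Ogun Ondo/Ekiti Oyo
Oyo 3 Kwara Ogun Osun
Rivers/Bayelsa 4 Abia Akwa_Ibom Delta Imo
Sokoto/Zamfara 4 Kaduna Katsina Kebbi Niger
Taraba 4 Adamawa Bauchi/Gombe Benue Nassarawa/Plateau
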